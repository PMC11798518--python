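"""Tabulated X-ray physics shared by every analysis stage.

Provides emission-line and absorption-edge registries for the elements
relevant to calcified-tissue work, mineral matrix definitions
(hydroxyapatite and its carbonated variants, whitlockite, calcium
carbonates, embedding paraffin), and mass attenuation coefficients from a
pinned Cromer-Liberman photoabsorption tabulation shipped with the
package.

Units follow beamline conventions: photon energies in keV, wavelengths in
nm, mass attenuation coefficients in cm^2/g, densities in g/cm^3 and
attenuation lengths in µm.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "HC_KEV_NM",
    "EmissionLine",
    "MatrixModel",
    "AttenuationTable",
    "TheoreticalFraction",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "energy_wavelength_convert",
    "default_table",
    "mass_attenuation",
    "attenuation_length",
    "theoretical_mass_fraction",
    "get_matrix",
    "emission_lines",
    "MATRIX_REGISTRY",
    "LINE_REGISTRY",
    "ATOMIC_MASS",
]

#: Planck constant times speed of light, keV * nm.
HC_KEV_NM = 1.239842

ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "O": 15.999, "Na": 22.990, "Mg": 24.305,
    "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45, "Ca": 40.078,
    "Sr": 87.62, "Y": 88.906,
}


# ---------------------------------------------------------------------------
# Unit conversions
# ---------------------------------------------------------------------------

def energy_to_wavelength(energy_kev: float) -> float:
    """Photon energy (keV) to wavelength (nm)."""
    if np.any(np.asarray(energy_kev) <= 0):
        raise ValueError("photon energy must be positive")
    return HC_KEV_NM / energy_kev


def wavelength_to_energy(wavelength_nm: float) -> float:
    """Photon wavelength (nm) to energy (keV)."""
    if np.any(np.asarray(wavelength_nm) <= 0):
        raise ValueError("wavelength must be positive")
    return HC_KEV_NM / wavelength_nm


def energy_wavelength_convert(value: float, direction: str) -> float:
    """Convert between photon energy and wavelength.

    direction: ``"energy_to_wavelength"`` (keV -> nm) or
    ``"wavelength_to_energy"`` (nm -> keV).
    """
    if direction == "energy_to_wavelength":
        return energy_to_wavelength(value)
    if direction == "wavelength_to_energy":
        return wavelength_to_energy(value)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# Emission lines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionLine:
    """One fluorescence line of an element.

    ``energy`` is the full-precision tabulated line energy in keV;
    ``edge`` is the binding energy (keV) of the shell that must be ionized
    for the line to be emitted; ``relative_intensity`` is the branching
    fraction within the series and ``fluor_yield`` the shell fluorescence
    yield.
    """

    element: str
    line_label: str
    energy: float
    relative_intensity: float
    edge: float
    fluor_yield: float
    series: str = "K"

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("line energy must be positive")
        if not 0 < self.relative_intensity <= 1:
            raise ValueError("relative intensity must be in (0, 1]")


# Full-precision line/edge energies (keV); the rounded values printed in map
# legends live in PRINTED_LINE_ENERGIES and are display metadata only.
LINE_REGISTRY: dict[str, tuple[EmissionLine, ...]] = {
    "O": (EmissionLine("O", "Ka", 0.5249, 1.0, 0.5437, 0.0083),),
    "Na": (EmissionLine("Na", "Ka", 1.0410, 1.0, 1.0721, 0.023),),
    "Mg": (EmissionLine("Mg", "Ka", 1.2536, 1.0, 1.3050, 0.030),),
    "Si": (
        EmissionLine("Si", "Ka", 1.7398, 0.98, 1.8389, 0.050),
        EmissionLine("Si", "Kb", 1.8359, 0.02, 1.8389, 0.050),
    ),
    "P": (
        EmissionLine("P", "Ka", 2.0137, 0.97, 2.1455, 0.063),
        EmissionLine("P", "Kb", 2.1391, 0.03, 2.1455, 0.063),
    ),
    "S": (
        EmissionLine("S", "Ka", 2.3078, 0.95, 2.4720, 0.078),
        EmissionLine("S", "Kb", 2.4640, 0.05, 2.4720, 0.078),
    ),
    "Cl": (
        EmissionLine("Cl", "Ka", 2.6224, 0.92, 2.8224, 0.097),
        EmissionLine("Cl", "Kb", 2.8156, 0.08, 2.8224, 0.097),
    ),
    "Ca": (
        EmissionLine("Ca", "Ka", 3.6917, 0.887, 4.0386, 0.163),
        EmissionLine("Ca", "Kb", 4.0127, 0.113, 4.0386, 0.163),
    ),
    "Sr": (
        EmissionLine("Sr", "La1", 1.8066, 0.65, 1.9396, 0.024, "L3"),
        EmissionLine("Sr", "Lb1", 1.8717, 0.35, 2.0068, 0.026, "L2"),
    ),
    "Y": (
        EmissionLine("Y", "La1", 1.9226, 0.65, 2.0800, 0.027, "L3"),
        EmissionLine("Y", "Lb1", 2.0056, 0.35, 2.1555, 0.028, "L2"),
    ),
}

#: Rounded line energies (keV) as printed in figure legends — display only.
PRINTED_LINE_ENERGIES = {
    ("Ca", "Ka"): 3.69, ("P", "Ka"): 2.01, ("Mg", "Ka"): 1.25,
    ("Na", "Ka"): 1.04, ("O", "Ka"): 0.52, ("Si", "Ka"): 1.74,
    ("Cl", "Ka"): 2.6, ("S", "Ka"): 2.3,
    ("Sr", "La1"): 1.806, ("Y", "La1"): 1.923,
}


def emission_lines(element: str) -> tuple[EmissionLine, ...]:
    """All registered fluorescence lines of an element."""
    try:
        return LINE_REGISTRY[element]
    except KeyError:
        raise KeyError(f"no emission lines registered for {element!r}") from None


# ---------------------------------------------------------------------------
# Matrix models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatrixModel:
    """Elemental composition and density of an assumed mineral matrix.

    ``reference_fractions`` holds the theoretical mass fractions the
    quantification is referenced to.  Where a printed constant exists it
    takes precedence over the value computed from ``composition`` (the two
    can disagree by a few percent depending on the assumed stoichiometry);
    see :func:`theoretical_mass_fraction`.
    """

    name: str
    composition: dict[str, float]
    density: float
    reference_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError("density must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"mass fractions sum to {total}, not 1")
        for w in self.composition.values():
            if not 0 <= w <= 1:
                raise ValueError("mass fractions must lie in [0, 1]")
        for el in self.reference_fractions:
            if el not in self.composition:
                raise ValueError(f"reference element {el} absent from composition")


def _from_formula(name: str, formula: dict[str, float], density: float,
                  reference_fractions: dict[str, float] | None = None) -> MatrixModel:
    masses = {el: n * ATOMIC_MASS[el] for el, n in formula.items()}
    total = sum(masses.values())
    comp = {el: m / total for el, m in masses.items()}
    # enforce exact closure against float round-off
    s = sum(comp.values())
    comp = {el: w / s for el, w in comp.items()}
    return MatrixModel(name, comp, density, reference_fractions or {})


MATRIX_REGISTRY: dict[str, MatrixModel] = {
    # Stoichiometric hydroxyapatite Ca10(PO4)6(OH)2, crystallographic density.
    "HAP": _from_formula(
        "HAP", {"Ca": 10, "P": 6, "O": 26, "H": 2}, 3.16,
        {"Ca": 0.39, "P": 0.196},
    ),
    # A-type carbonated apatite: carbonate on the hydroxyl site.
    "HAP_A": _from_formula(
        "HAP_A", {"Ca": 10, "P": 6, "O": 27, "C": 1}, 3.10,
        {"Ca": 0.39, "P": 0.182},
    ),
    # B-type carbonated apatite: carbonate on the phosphate site
    # (Ca10(PO4)5.35(CO3)0.65(OH)2 reproduces the 16.9 % reference P fraction).
    "HAP_B": _from_formula(
        "HAP_B", {"Ca": 10, "P": 5.35, "C": 0.65, "O": 25.35, "H": 2}, 3.06,
        {"Ca": 0.39, "P": 0.169},
    ),
    # Whitlockite Ca9Mg(PO4)6(HPO4).
    "WHIT": _from_formula(
        "WHIT", {"Ca": 9, "Mg": 1, "P": 7, "O": 28, "H": 1}, 3.12,
        {"Mg": 0.023, "P": 0.184},
    ),
    "CALCITE": _from_formula("CALCITE", {"Ca": 1, "C": 1, "O": 3}, 2.71),
    # Monohydrated amorphous calcium carbonate at a nominal amorphous density.
    "ACC": _from_formula("ACC", {"Ca": 1, "C": 1, "O": 4, "H": 2}, 2.0),
    "PARAFFIN": _from_formula("PARAFFIN", {"C": 1, "H": 2}, 0.90),
}


def get_matrix(name: str) -> MatrixModel:
    try:
        return MATRIX_REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown matrix {name!r}; known: {sorted(MATRIX_REGISTRY)}") from None


# ---------------------------------------------------------------------------
# Attenuation
# ---------------------------------------------------------------------------

class AttenuationTable:
    """Per-element mass attenuation coefficients with log-log interpolation.

    The shipped tabulation (``data/attenuation_cl.csv``) holds
    photoabsorption coefficients on a geometric energy grid from 0.2 to
    25 keV with extra points bracketing each absorption edge, so piecewise
    log-log interpolation reproduces the grid exactly, stays monotone
    between grid points and respects edge discontinuities.
    """

    def __init__(self, rows: dict[str, tuple[np.ndarray, np.ndarray]],
                 provenance: str = "cromer-liberman-pinned"):
        self.provenance = provenance
        self._log: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._range: dict[str, tuple[float, float]] = {}
        for el, (e, mu) in rows.items():
            e = np.asarray(e, dtype=float)
            mu = np.asarray(mu, dtype=float)
            if np.any(np.diff(e) <= 0):
                raise ValueError(f"energy grid for {el} not strictly increasing")
            if np.any(mu <= 0):
                raise ValueError(f"non-positive coefficient for {el}")
            self._log[el] = (np.log(e), np.log(mu))
            self._range[el] = (float(e[0]), float(e[-1]))

    @classmethod
    def from_csv(cls, path) -> "AttenuationTable":
        rows: dict[str, list[tuple[float, float]]] = {}
        with open(path, newline="") as fh:
            for rec in csv.DictReader(fh):
                rows.setdefault(rec["element"], []).append(
                    (float(rec["energy_keV"]), float(rec["mu_rho_cm2_g"]))
                )
        arrs = {}
        for el, pairs in rows.items():
            pairs.sort()
            e, mu = zip(*pairs)
            arrs[el] = (np.array(e), np.array(mu))
        return cls(arrs)

    @property
    def elements(self) -> list[str]:
        return sorted(self._log)

    def energy_range(self, element: str) -> tuple[float, float]:
        return self._range[element]

    def element_mu(self, element: str, energy_kev) -> np.ndarray | float:
        """Mass attenuation coefficient (cm^2/g) of one element."""
        if element not in self._log:
            raise KeyError(f"element {element!r} not tabulated")
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self._range[element]
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy {energy_kev} keV outside tabulated range "
                f"[{lo:.3g}, {hi:.3g}] for {element}"
            )
        loge, logmu = self._log[element]
        out = np.exp(np.interp(np.log(e), loge, logmu))
        return float(out) if np.isscalar(energy_kev) else out


@lru_cache(maxsize=1)
def default_table() -> AttenuationTable:
    """The tabulation shipped with the package."""
    ref = resources.files("mcspec") / "data" / "attenuation_cl.csv"
    with resources.as_file(ref) as path:
        return AttenuationTable.from_csv(path)


def mass_attenuation(matrix: MatrixModel, energy_kev,
                     table: AttenuationTable | None = None):
    """Mass attenuation coefficient of a matrix by the mixture rule.

    mu/rho = sum_i w_i (mu/rho)_i, in cm^2/g.
    """
    table = table or default_table()
    return sum(w * table.element_mu(el, energy_kev)
               for el, w in matrix.composition.items())


def attenuation_length(matrix: MatrixModel, energy_kev,
                       table: AttenuationTable | None = None):
    """1/e attenuation length in µm at normal incidence.

    delta = 1 / (rho * mu/rho), converted from cm to µm.
    """
    mu = mass_attenuation(matrix, energy_kev, table)
    return 1e4 / (matrix.density * mu)


@dataclass(frozen=True)
class TheoreticalFraction:
    """Reference mass fraction with provenance.

    ``value`` is what quantification should use: the registry (printed)
    constant when one exists, otherwise the stoichiometric value.
    ``consistent`` flags whether the two agree within 10 % (None when no
    registry constant exists).
    """

    element: str
    value: float
    registry: float | None
    computed: float
    consistent: bool | None

    def __float__(self) -> float:
        return self.value


def theoretical_mass_fraction(matrix: MatrixModel, element: str) -> TheoreticalFraction:
    """Reference mass fraction of an element in a matrix."""
    if element not in matrix.composition:
        raise KeyError(f"{element} not in composition of {matrix.name}")
    computed = matrix.composition[element]
    registry = matrix.reference_fractions.get(element)
    if registry is None:
        return TheoreticalFraction(element, computed, None, computed, None)
    consistent = abs(registry - computed) <= 0.1 * registry
    return TheoreticalFraction(element, registry, registry, computed, consistent)
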