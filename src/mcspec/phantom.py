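"""Synthetic microcalcification scenes and their multi-modal renderers.

A :class:`PhantomScene` is a small raster scene with four region types —
embedding background, a thin periphery, the deposit core and (for the
benign preset) a whitlockite/Mg-enriched rim ring — each carrying a
thickness, a matrix mixture, trace-element mass fractions, WAXS phase
content and XANES species weights.  One ground-truth description is
rendered into every modality the analysis consumes: transmission maps,
XRF spectrum cubes at 2.1/2.5/4.2 keV, XANES point spectra with their
reference library, and per-pixel WAXS profiles.

Preset numbers emulate the reported study conditions: deposits 3-5 µm
effective thickness in a 0.5-1 µm periphery; a benign rim with
whitlockite and Mg approaching its 2.3 % theoretical fraction; DCIS with
high-crystallinity apatite and Mg patches peaking near 3 %; IDC with the
lowest Mg and elevated Na; traces Na 0.005-0.02, S 0.001-0.01,
Cl 0.002-0.004, with more Y than Sr.  Noise models: Poisson counting
noise on spectra and profiles, optional multiplicative Gaussian noise on
transmission.  All renderers are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .physics import MatrixModel, get_matrix, mass_attenuation
from .waxs import (HAP_LOW_CRYSTALLINITY, HAP_PHASE, WHIT_PHASE, PhaseModel,
                   Profile1D, synthesize_profile)
from .xanes import ReferenceSet, XanesSpectrum, make_reference_set
from .xrf import DetectorModel, GeometryModel, SpectrumCube, simulate_spectrum

__all__ = [
    "RegionSpec",
    "PhantomScene",
    "build_scene",
    "render_transmission",
    "render_xrf_cube",
    "render_xanes",
    "render_waxs",
    "BACKGROUND",
    "PERIPHERY",
    "CORE",
    "RIM",
]

BACKGROUND, PERIPHERY, CORE, RIM = 0, 1, 2, 3
_REGION_NAMES = {BACKGROUND: "background", PERIPHERY: "periphery",
                 CORE: "core", RIM: "rim"}


@dataclass(frozen=True)
class RegionSpec:
    """Ground truth of one scene region."""

    name: str
    thickness_um: float
    matrix_mix: dict[str, float]          # matrix name -> mixture fraction
    traces: dict[str, float] = field(default_factory=dict)
    phases: tuple[tuple[PhaseModel, float], ...] = ()
    xanes_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.matrix_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"matrix mixture of {self.name} sums to {total}")
        if self.thickness_um < 0:
            raise ValueError("negative thickness")
        for name in self.matrix_mix:
            get_matrix(name)   # raises on unknown matrix

    def composition(self) -> dict[str, float]:
        """Element mass fractions: mixture of matrices with traces overlaid."""
        base: dict[str, float] = {}
        for mname, f in self.matrix_mix.items():
            for el, w in get_matrix(mname).composition.items():
                base[el] = base.get(el, 0.0) + f * w
        t_total = sum(self.traces.values())
        comp = {el: w * (1.0 - t_total) for el, w in base.items()}
        for el, w in self.traces.items():
            comp[el] = comp.get(el, 0.0) + w
        return comp


@dataclass
class PhantomScene:
    """Raster scene with per-pixel region labels, thickness and ground truth."""

    shape: tuple[int, int]
    pixel_size_um: float
    region_label: np.ndarray
    thickness_um: np.ndarray
    regions: dict[int, RegionSpec]
    seed: int
    preset: str
    mg_map: np.ndarray | None = None     # per-pixel Mg fraction (patchy presets)

    def region_mask(self, label: int) -> np.ndarray:
        return self.region_label == label

    def pixel_traces(self, r: int, c: int) -> dict[str, float]:
        traces = dict(self.regions[int(self.region_label[r, c])].traces)
        if self.mg_map is not None and "Mg" in traces:
            traces["Mg"] = float(self.mg_map[r, c])
        return traces

    def pixel_composition(self, r: int, c: int) -> dict[str, float]:
        spec = self.regions[int(self.region_label[r, c])]
        if self.mg_map is None:
            return spec.composition()
        return replace(spec, traces=self.pixel_traces(r, c)).composition()


def _scene_geometry(shape: tuple[int, int], rng: np.random.Generator,
                    with_rim: bool) -> tuple[np.ndarray, np.ndarray]:
    """Elliptical deposit with rim ring and periphery halo; returns
    (region labels, radial coordinate normalized to the core edge)."""
    rows, cols = shape
    rr, cc = np.indices(shape)
    r0, c0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    ar, ac = 0.30 * rows, 0.36 * cols        # core semi-axes, px
    rho = np.sqrt(((rr - r0) / ar) ** 2 + ((cc - c0) / ac) ** 2)
    labels = np.full(shape, BACKGROUND, dtype=int)
    labels[rho <= 1.0] = CORE
    if with_rim:
        labels[(rho > 1.0) & (rho <= 1.22)] = RIM
        labels[(rho > 1.22) & (rho <= 1.55)] = PERIPHERY
    else:
        labels[(rho > 1.0) & (rho <= 1.55)] = PERIPHERY
    return labels, rho


_PRESETS = ("benign", "dcis", "idc")


def build_scene(preset: str, seed: int, shape: tuple[int, int] = (64, 64),
                pixel_size_um: float = 2.0) -> PhantomScene:
    """Construct a ground-truth scene for one disease preset.

    benign: low-crystallinity apatite core with a whitlockite/Mg rim and
    carbonate-rich thin regions; dcis: high-crystallinity apatite with
    patchy Mg peaking near 0.03, no rim; idc: high-crystallinity apatite,
    lowest Mg, elevated Na, no whitlockite anywhere.
    """
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {_PRESETS}")
    rng = np.random.default_rng(seed)
    with_rim = preset == "benign"
    labels, rho = _scene_geometry(shape, rng, with_rim)

    paraffin = {"PARAFFIN": 1.0}
    if preset == "benign":
        core_phase = ((HAP_LOW_CRYSTALLINITY, 1.0),)
        core_xanes = {"HAP": 0.50, "HAP_A": 0.12, "HAP_B": 0.11,
                      "WHIT": 0.09, "ACC": 0.14, "CALCITE": 0.04}
        core_traces = {"Na": 0.008, "Mg": 0.012, "S": 0.002, "Cl": 0.003,
                       "Sr": 0.0002, "Y": 0.0005}
        regions = {
            BACKGROUND: RegionSpec("background", 0.08, paraffin),
            PERIPHERY: RegionSpec(
                "periphery", 0.75,
                {"HAP_B": 0.60, "ACC": 0.40},
                {"Na": 0.008, "Mg": 0.015, "S": 0.008, "Cl": 0.004,
                 "Sr": 0.0002, "Y": 0.0005},
                ((HAP_LOW_CRYSTALLINITY, 0.3),),
                {"HAP": 0.10, "HAP_A": 0.04, "HAP_B": 0.04, "WHIT": 0.30,
                 "ACC": 0.46, "CALCITE": 0.06},
            ),
            CORE: RegionSpec("core", 4.0, {"HAP_B": 0.92, "ACC": 0.08},
                             core_traces, core_phase, core_xanes),
            RIM: RegionSpec(
                "rim", 1.3,
                {"HAP_B": 0.55, "WHIT": 0.30, "ACC": 0.15},
                {"Na": 0.008, "Mg": 0.018, "S": 0.006, "Cl": 0.004,
                 "Sr": 0.0002, "Y": 0.0005},
                ((WHIT_PHASE, 0.6), (HAP_LOW_CRYSTALLINITY, 0.4)),
                {"HAP": 0.08, "HAP_A": 0.04, "HAP_B": 0.03, "WHIT": 0.35,
                 "ACC": 0.45, "CALCITE": 0.05},
            ),
        }
    else:
        hi = ((HAP_PHASE, 1.0),)
        if preset == "dcis":
            core_traces = {"Na": 0.012, "Mg": 0.015, "S": 0.002, "Cl": 0.003,
                           "Sr": 0.0002, "Y": 0.0005}
        else:
            core_traces = {"Na": 0.02, "Mg": 0.008, "S": 0.006, "Cl": 0.003,
                           "Sr": 0.0002, "Y": 0.0005}
        core_xanes = {"HAP": 0.60, "HAP_A": 0.14, "HAP_B": 0.16,
                      "ACC": 0.08, "CALCITE": 0.02}
        regions = {
            BACKGROUND: RegionSpec("background", 0.08, paraffin),
            PERIPHERY: RegionSpec(
                "periphery", 0.75, {"HAP_B": 0.75, "ACC": 0.25},
                {**core_traces, "S": 0.008 if preset == "dcis" else 0.004},
                ((HAP_PHASE, 0.3),),
                {"HAP": 0.45, "HAP_A": 0.10, "HAP_B": 0.12,
                 "ACC": 0.28, "CALCITE": 0.05},
            ),
            CORE: RegionSpec("core", 4.0, {"HAP_B": 0.95, "ACC": 0.05},
                             core_traces, hi, core_xanes),
        }

    # smooth thickness relief in the deposit: 3-5 µm, thinning to the edge
    thick = np.full(shape, regions[BACKGROUND].thickness_um)
    core = labels == CORE
    relief = 5.0 - 2.0 * np.clip(rho, 0.0, 1.0) ** 2     # 5 µm centre, 3 µm edge
    thick[core] = relief[core]
    for lbl in (PERIPHERY, RIM):
        if lbl in regions:
            m = labels == lbl
            thick[m] = regions[lbl].thickness_um
    thick *= 1.0 + 0.03 * rng.standard_normal(shape)
    thick = np.clip(thick, 0.0, None)

    mg_map = None
    if preset == "dcis":
        # patchy Mg: smooth random field scaled into [base, 0.03]
        base = regions[CORE].traces["Mg"]
        f = rng.standard_normal(shape)
        k = np.ones((7, 7)) / 49.0
        from scipy.signal import convolve2d
        f = convolve2d(f, k, mode="same", boundary="symm")
        f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
        mg_map = base + (0.03 - base) * f

    return PhantomScene(shape, pixel_size_um, labels, thick, regions,
                        seed, preset, mg_map)


# ---------------------------------------------------------------------------
# Renderers
# ---------------------------------------------------------------------------

def _pixel_mu_linear(scene: PhantomScene, e_in: float) -> np.ndarray:
    """Per-pixel linear attenuation coefficient (1/cm) of the matrix mix.

    Mixed-matrix pixels are layer-homogeneous: the mixture fraction acts
    as an equivalent-thickness share of each matrix.
    """
    mu = np.zeros(scene.shape)
    for lbl, spec in scene.regions.items():
        m = scene.region_mask(lbl)
        if not m.any():
            continue
        val = sum(f * mass_attenuation(get_matrix(n), e_in) * get_matrix(n).density
                  for n, f in spec.matrix_mix.items())
        mu[m] = val
    return mu


def render_transmission(scene: PhantomScene, e_in: float,
                        noise_sigma: float = 0.0,
                        rng: np.random.Generator | None = None) -> np.ndarray:
    """Beer-Lambert transmission map I/I0 at the given energy."""
    mu = _pixel_mu_linear(scene, e_in)
    trans = np.exp(-mu * scene.thickness_um * 1e-4)
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(scene.seed + 1)
        trans = trans * (1.0 + noise_sigma * rng.standard_normal(scene.shape))
    return np.clip(trans, 1e-12, None)


def render_xrf_cube(scene: PhantomScene, e_in: float,
                    det: DetectorModel | None = None,
                    geom: GeometryModel | None = None,
                    counts_scale: float = 5000.0,
                    live_time_s: float = 6.0,
                    seed: int | None = None,
                    poisson: bool = True,
                    transmission_noise: float = 0.0) -> SpectrumCube:
    """Render the XRF spectrum cube with attached transmission.

    Each pixel is forward-modelled with its ground-truth composition and
    thickness under the analysis matrix assumption of that region's
    dominant matrix; counting noise is Poisson.
    """
    det = det or DetectorModel()
    geom = geom or GeometryModel()
    rng = np.random.default_rng(scene.seed + 10 if seed is None else seed)
    rows, cols = scene.shape
    counts = np.empty((rows, cols, det.n_channels))
    # cache spectra per (region, thickness rounded, Mg rounded) for speed
    cache: dict[tuple, np.ndarray] = {}
    for r in range(rows):
        for c in range(cols):
            lbl = int(scene.region_label[r, c])
            t = round(float(scene.thickness_um[r, c]), 2)
            mg = (round(float(scene.mg_map[r, c]), 4)
                  if scene.mg_map is not None else None)
            key = (lbl, t, mg)
            if key not in cache:
                spec = scene.regions[lbl]
                comp = scene.pixel_composition(r, c)
                matrix = get_matrix(max(spec.matrix_mix, key=spec.matrix_mix.get))
                cache[key] = simulate_spectrum(
                    comp, t, matrix, e_in, det, geom,
                    counts_scale=counts_scale, poisson=False)
            clean = cache[key]
            counts[r, c] = rng.poisson(clean) if poisson else clean
    trans = render_transmission(scene, e_in, transmission_noise,
                                np.random.default_rng(scene.seed + 11))
    return SpectrumCube(counts, e_in, det.gain_kev, det.offset_kev,
                        live_time_s, transmission=trans, i0=1.0)


def render_xanes(scene: PhantomScene, positions,
                 grid: np.ndarray | None = None,
                 noise_sigma: float = 0.0,
                 rng: np.random.Generator | None = None
                 ) -> tuple[list[XanesSpectrum], ReferenceSet]:
    """Point XANES spectra at scan positions plus the reference library.

    Each spectrum is the region's ground-truth species mixture of the
    parametric references with optional additive Gaussian noise; thick
    positions are tagged transmission-mode, thin ones fluorescence-mode.
    """
    refs = make_reference_set(grid)
    rng = rng or np.random.default_rng(scene.seed + 20)
    out = []
    g = refs.grid
    for (r, c) in positions:
        spec = scene.regions[int(scene.region_label[r, c])]
        w = spec.xanes_weights
        if not w:
            w = {"ACC": 1.0}
        total = sum(w.values())
        mu = np.zeros_like(g)
        for name, wi in w.items():
            mu += (wi / total) * refs.spectra[name].mu
        if noise_sigma > 0:
            mu = mu + noise_sigma * rng.standard_normal(len(g))
        mode = ("transmission" if scene.thickness_um[r, c] > 2.0
                else "fluorescence")
        out.append(XanesSpectrum(g, mu, mode=mode, normalized=True,
                                 name=f"{scene.preset}_{r}_{c}"))
    return out, refs


def render_waxs(scene: PhantomScene, q_nm: np.ndarray | None = None,
                counts_scale: float = 200.0,
                seed: int | None = None,
                poisson: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel WAXS profiles; returns (profiles array, q grid).

    Each region's phase content is synthesized once (pseudo-Voigt whole
    patterns); pixels scale it by thickness and add a smooth amorphous
    background hump before Poisson sampling.
    """
    if q_nm is None:
        q_nm = np.linspace(5.5, 35.0, 600)
    q_nm = np.asarray(q_nm, dtype=float)
    rng = np.random.default_rng(scene.seed + 30 if seed is None else seed)
    hump = 0.3 + 0.7 * np.exp(-0.5 * ((q_nm - 14.0) / 7.0) ** 2)
    base = {}
    for lbl, spec in scene.regions.items():
        prof = np.zeros_like(q_nm)
        for phase, wgt in spec.phases:
            prof += wgt * synthesize_profile(q_nm, phase)
        base[lbl] = prof
    rows, cols = scene.shape
    profiles = np.empty((rows * cols, len(q_nm)))
    labels = scene.region_label.ravel()
    thick = scene.thickness_um.ravel()
    for i in range(rows * cols):
        clean = counts_scale * (thick[i] * base[int(labels[i])] + 0.5 * hump)
        profiles[i] = rng.poisson(clean) if poisson else clean
    return profiles, q_nm
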