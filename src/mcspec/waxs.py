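"""WAXS/SAXS profile analysis for mineral phase mapping.

Covers azimuthal integration of 2D detector frames into 1D profiles
I(q), a least-correlated-profile classification of raster scans, peak
positions of the hexagonal apatite and rhombohedral whitlockite cells,
simplified whole-pattern refinement (free peak intensities, refined cell
and anisotropic crystalline domain sizes), and collagen D-spacing from
equally spaced SAXS orders.

Momentum transfer q = (4 pi / lambda) sin(theta) is carried in nm^-1;
cell parameters and domain sizes in Å as is conventional for these
phases.  In q-space the Scherrer relation takes the angle-free form
beta_q = 2 pi K / D, which the width model relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, nnls
from scipy.signal import find_peaks

__all__ = [
    "Profile1D",
    "PhaseModel",
    "Reflection",
    "ClassificationResult",
    "RefinementResult",
    "DSpacingResult",
    "HAP_PHASE",
    "HAP_LOW_CRYSTALLINITY",
    "WHIT_PHASE",
    "azimuthal_integrate",
    "classify_profiles",
    "phase_peak_positions",
    "synthesize_profile",
    "refine_profile",
    "ProfileRefinement",
    "collagen_d_spacing",
    "domain_size_from_width",
    "width_from_domain_size",
]


@dataclass
class Profile1D:
    """One azimuthally integrated scattering profile."""

    q_nm: np.ndarray
    intensity: np.ndarray
    segment: int | None = None
    pixel: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.q_nm = np.asarray(self.q_nm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.q_nm) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")


@dataclass(frozen=True)
class Reflection:
    hkl: tuple[int, int, int]
    q_nm: float
    multiplicity: int = 1


@dataclass(frozen=True)
class PhaseModel:
    """Hexagonal-setting cell with two-direction anisotropic domain sizes.

    ``domain_002`` and ``domain_110`` (Å) are the crystalline domain sizes
    along the c axis and in the basal plane; peak widths interpolate
    between them by the angle of the scattering vector to c*.  For the
    rhombohedral whitlockite cell (hexagonal setting) the obverse
    reflection condition -h + k + l = 3n applies and a single isotropic
    domain size is used (``domain_110 = domain_002``).
    """

    name: str
    a: float                    # Å, a = b
    c: float                    # Å
    domain_002: float           # Å
    domain_110: float           # Å
    rhombohedral: bool = False
    scherrer_k: float = 0.9
    eta: float = 0.5            # pseudo-Voigt mixing

    def __post_init__(self) -> None:
        if self.a <= 0 or self.c <= 0:
            raise ValueError("cell parameters must be positive")
        if self.domain_002 <= 0 or self.domain_110 <= 0:
            raise ValueError("domain sizes must be positive")

    @property
    def isotropic(self) -> bool:
        return self.domain_002 == self.domain_110


# Refined parameters of the recurring phases (hexagonal apatite at two
# crystallinity levels, and whitlockite).
HAP_PHASE = PhaseModel("HAP", 9.3897, 6.8652, 244.0, 129.0)
HAP_LOW_CRYSTALLINITY = PhaseModel("HAP_LC", 9.3897, 6.8652, 96.0, 53.0)
WHIT_PHASE = PhaseModel("WHIT", 10.3211, 36.9674, 46.0, 46.0, rhombohedral=True)


# ---------------------------------------------------------------------------
# Peak geometry
# ---------------------------------------------------------------------------

def _inv_d2(h: int, k: int, l: int, a: float, c: float) -> float:
    return (4.0 / 3.0) * (h * h + h * k + k * k) / (a * a) + l * l / (c * c)


def phase_peak_positions(phase: PhaseModel, q_max_nm: float,
                         q_min_nm: float = 0.0) -> list[Reflection]:
    """Allowed reflections up to ``q_max_nm``, sorted by q.

    Hexagonal-setting spacing 1/d^2 = (4/3)(h^2+hk+k^2)/a^2 + l^2/c^2 and
    q = 2 pi / d.  For rhombohedral phases only hkl with -h+k+l = 3n
    (obverse setting) survive; symmetry-equivalent indices are grouped
    into one powder line with its multiplicity.
    """
    a, c = phase.a, phase.c
    hmax = int(math.ceil(q_max_nm / 10.0 * a / (2.0 * math.pi) * 1.2)) + 1
    lmax = int(math.ceil(q_max_nm / 10.0 * c / (2.0 * math.pi))) + 1
    found: dict[float, tuple[float, list[tuple[int, int, int]]]] = {}
    for h in range(-hmax, hmax + 1):
        for k in range(-hmax, hmax + 1):
            for l in range(-lmax, lmax + 1):
                if h == 0 and k == 0 and l == 0:
                    continue
                if phase.rhombohedral and (-h + k + l) % 3 != 0:
                    continue
                q = 2.0 * math.pi * math.sqrt(_inv_d2(h, k, l, a, c)) * 10.0
                if not q_min_nm < q <= q_max_nm:
                    continue
                key = round(q, 6)
                if key in found:
                    found[key][1].append((h, k, l))
                else:
                    found[key] = (q, [(h, k, l)])
    out = []
    for key in sorted(found):
        q, hkls = found[key]
        rep = max(hkls, key=lambda t: (t[0] >= t[1] >= 0, t[2] >= 0, t))
        out.append(Reflection(rep, q, len(hkls)))
    return out


def width_from_domain_size(phase: PhaseModel, refl: Reflection) -> float:
    """Scherrer FWHM in q (nm^-1) for one reflection.

    In q-space the Scherrer relation is beta_q = 2 pi K / D; the
    direction-dependent size interpolates the inverse sizes by the angle
    phi between the scattering vector and c*:
    1/D(hkl) = cos^2(phi)/D_002 + sin^2(phi)/D_110.
    """
    h, k, l = refl.hkl
    inv_d = math.sqrt(_inv_d2(h, k, l, phase.a, phase.c))
    cos2 = (l / phase.c) ** 2 / inv_d**2 if inv_d > 0 else 0.0
    inv_size = cos2 / phase.domain_002 + (1.0 - cos2) / phase.domain_110
    return 2.0 * math.pi * phase.scherrer_k * inv_size * 10.0   # Å^-1 -> nm^-1


def domain_size_from_width(phase: PhaseModel, refl: Reflection,
                           fwhm_q_nm: float) -> float:
    """Invert the q-space Scherrer relation for one reflection (Å)."""
    return 2.0 * math.pi * phase.scherrer_k / (fwhm_q_nm / 10.0)


def _pseudo_voigt(q: np.ndarray, q0: float, fwhm: float, eta: float) -> np.ndarray:
    """Unit-area pseudo-Voigt profile."""
    hwhm = fwhm / 2.0
    lor = (hwhm / math.pi) / ((q - q0) ** 2 + hwhm**2)
    sig = fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    gau = np.exp(-0.5 * ((q - q0) / sig) ** 2) / (sig * math.sqrt(2.0 * math.pi))
    return eta * lor + (1.0 - eta) * gau


def _default_intensities(reflections: list[Reflection]) -> np.ndarray:
    """Falling-with-q free intensities used when none are specified."""
    return np.array([r.multiplicity / (1.0 + (r.q_nm / 15.0) ** 2)
                     for r in reflections])


def synthesize_profile(q_nm: np.ndarray, phases, intensities=None,
                       background: np.ndarray | None = None,
                       inst_fwhm_nm: float = 0.0) -> np.ndarray:
    """Whole-pattern forward model: pseudo-Voigt peaks at the phase
    positions with Scherrer widths (instrumental width added in
    quadrature) plus an optional fixed background."""
    q = np.asarray(q_nm, dtype=float)
    out = np.zeros_like(q) if background is None else np.array(background, dtype=float)
    if isinstance(phases, PhaseModel):
        phases = [phases]
    if intensities is None:
        intensities = [None] * len(phases)
    for phase, inten in zip(phases, intensities):
        refs = phase_peak_positions(phase, q.max() + 1.0, max(q.min() - 1.0, 0.0))
        amps = _default_intensities(refs) if inten is None else np.asarray(inten, float)
        for r, ampl in zip(refs, amps):
            fwhm = math.hypot(width_from_domain_size(phase, r), inst_fwhm_nm)
            out += ampl * _pseudo_voigt(q, r.q_nm, fwhm, phase.eta)
    return out


# ---------------------------------------------------------------------------
# Whole-pattern refinement
# ---------------------------------------------------------------------------

@dataclass
class RefinementResult:
    """Refined phases with free intensities and the fit report."""

    phases: list[PhaseModel]
    intensities: list[np.ndarray]
    cost: float
    success: bool
    n_iterations: int
    message: str
    flags: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = ["whole-pattern refinement", "=" * 46]
        for p in self.phases:
            lines.append(f"{p.name:<10} a = {p.a:9.4f} Å  c = {p.c:9.4f} Å  "
                         f"D[002] = {p.domain_002:6.1f} Å  D[110] = {p.domain_110:6.1f} Å")
        lines.append(f"cost = {self.cost:.6g}  converged = {self.success}"
                     f"  ({self.n_iterations} evaluations)")
        lines.extend(f"flag: {f}" for f in self.flags)
        return "\n".join(lines)


class ProfileRefinement:
    """Least-squares whole-pattern fit of cell and domain sizes.

    Free parameters per phase: a, c and the log domain sizes (a single
    size for isotropic phases); peak intensities are profiled out at each
    step by non-negative least squares (free-intensity fit — no
    structure-factor model).  The background is fixed, interpolated
    through anchor points, and never refined; an instrumental resolution
    width (from a standard-powder calibration) is added in quadrature in
    the model and therefore deconvolved from the refined sizes.
    """

    def __init__(self, profile: Profile1D, phases,
                 background: np.ndarray | None = None,
                 background_anchors_q=None,
                 inst_fwhm_nm: float = 0.0,
                 q_range: tuple[float, float] | None = None):
        if isinstance(phases, PhaseModel):
            phases = [phases]
        self.profile = profile
        self.start = list(phases)
        self.inst_fwhm = float(inst_fwhm_nm)
        q = profile.q_nm
        sel = np.ones_like(q, dtype=bool)
        if q_range is not None:
            sel = (q >= q_range[0]) & (q <= q_range[1])
        self.q = q[sel]
        y = profile.intensity[sel]
        if background is not None:
            bg = np.asarray(background, dtype=float)[sel]
        elif background_anchors_q is not None:
            anchors = np.asarray(background_anchors_q, dtype=float)
            vals = np.interp(anchors, q, profile.intensity)
            bg = np.interp(self.q, anchors, vals)
        else:
            bg = np.zeros_like(self.q)
        self.y = y - bg
        for p in self.start:
            n = len(phase_peak_positions(p, self.q.max(), self.q.min()))
            if n < 3:
                raise ValueError(
                    f"phase {p.name} has only {n} reflections in range; need >= 3")

    # -- parameter packing --------------------------------------------------
    def _pack(self, phases) -> np.ndarray:
        x = []
        for p in phases:
            x.extend([p.a, p.c, math.log(p.domain_002)])
            if not p.isotropic:
                x.append(math.log(p.domain_110))
        return np.array(x)

    def _unpack(self, x) -> list[PhaseModel]:
        out = []
        i = 0
        for p in self.start:
            a, c, ld2 = x[i], x[i + 1], x[i + 2]
            i += 3
            if p.isotropic:
                d110 = math.exp(ld2)
            else:
                d110 = math.exp(x[i])
                i += 1
            out.append(replace(p, a=float(a), c=float(c),
                               domain_002=float(math.exp(ld2)),
                               domain_110=float(d110)))
        return out

    #: Reflections this far (nm^-1) outside the fit window still contribute
    #: tail intensity and are kept in the basis.
    BASIS_MARGIN_NM = 2.0

    def _basis(self, phases) -> tuple[np.ndarray, list[int]]:
        cols = []
        counts = []
        for p in phases:
            refs = phase_peak_positions(
                p, self.q.max() + self.BASIS_MARGIN_NM,
                max(self.q.min() - self.BASIS_MARGIN_NM, 0.0))
            counts.append(len(refs))
            for r in refs:
                fwhm = math.hypot(width_from_domain_size(p, r), self.inst_fwhm)
                cols.append(_pseudo_voigt(self.q, r.q_nm, fwhm, p.eta))
        return np.column_stack(cols), counts

    def _residual(self, x) -> np.ndarray:
        phases = self._unpack(x)
        basis, _ = self._basis(phases)
        amps, _ = nnls(basis, self.y)
        return basis @ amps - self.y

    def _prescan(self, x0: np.ndarray) -> np.ndarray:
        """Coarse grid over lattice scale factors before the local solve.

        With many overlapping reflections and free intensities the
        least-squares landscape has shallow false valleys: a slightly
        wrong cell is partly absorbed by re-weighting neighbouring
        peaks.  Scanning a global scale on a and on c (intensities
        profiled out by NNLS at each node) places the start inside the
        true basin.
        """
        if len(self.start) != 1:
            return x0
        scales = np.linspace(0.975, 1.025, 11)
        best_x, best_cost = x0, float(np.sum(self._residual(x0) ** 2))
        for sa in scales:
            for sc in scales:
                x = x0.copy()
                x[0] = x0[0] * sa
                x[1] = x0[1] * sc
                cost = float(np.sum(self._residual(x) ** 2))
                if cost < best_cost:
                    best_x, best_cost = x, cost
        return best_x

    def fit(self, prescan: bool = True) -> RefinementResult:
        x0 = self._pack(self.start)
        if prescan:
            x0 = self._prescan(x0)
        # central differences and Jacobian scaling matter here: the
        # free-intensity valley is stiff along c for densely overlapping
        # patterns
        res = least_squares(self._residual, x0, method="trf",
                            jac="3-point", x_scale="jac",
                            xtol=1e-15, ftol=1e-15, gtol=1e-15,
                            max_nfev=4000)
        phases = self._unpack(res.x)
        basis, counts = self._basis(phases)
        amps, _ = nnls(basis, self.y)
        intensities = []
        i = 0
        for n in counts:
            intensities.append(amps[i:i + n])
            i += n
        flags = []
        sv = np.linalg.svd(basis, compute_uv=False)
        if sv[-1] <= 0 or sv[0] / sv[-1] > 1e10:
            flags.append("severely overlapping reflections")
        if not res.success:
            flags.append("non-convergence: reporting last iterate")
        return RefinementResult(phases, intensities, float(res.cost),
                                bool(res.success), int(res.nfev), res.message,
                                flags)


def refine_profile(profile: Profile1D, phases, **kw) -> RefinementResult:
    """Refine cell and domain sizes; see :class:`ProfileRefinement`."""
    return ProfileRefinement(profile, phases, **kw).fit()


# ---------------------------------------------------------------------------
# Azimuthal integration
# ---------------------------------------------------------------------------

def azimuthal_integrate(frame: np.ndarray, beam_center: tuple[float, float],
                        pixel_size_mm: float, distance_mm: float,
                        wavelength_nm: float, n_segments: int = 16,
                        n_qbins: int = 400,
                        q_range: tuple[float, float] | None = None,
                        mask: np.ndarray | None = None):
    """Integrate a 2D frame into per-segment and full-average 1D profiles.

    q = (4 pi / lambda) sin(theta) with 2 theta = atan(r / L).  Returns
    (segment_profiles, average_profile); segment index runs over
    ``n_segments`` equal azimuthal wedges.
    """
    frame = np.asarray(frame, dtype=float)
    r0, c0 = beam_center
    nr, nc = frame.shape
    if not (0 <= r0 < nr and 0 <= c0 < nc):
        raise ValueError("beam center outside frame")
    rows, cols = np.indices(frame.shape)
    dy = (rows - r0) * pixel_size_mm
    dx = (cols - c0) * pixel_size_mm
    r_mm = np.hypot(dx, dy)
    theta = 0.5 * np.arctan2(r_mm, distance_mm)
    q = 4.0 * math.pi / wavelength_nm * np.sin(theta)
    azim = np.mod(np.arctan2(dy, dx), 2.0 * math.pi)
    seg = np.minimum((azim / (2.0 * math.pi) * n_segments).astype(int),
                     n_segments - 1)
    valid = np.ones(frame.shape, dtype=bool) if mask is None else ~mask
    valid &= r_mm > 0
    if q_range is None:
        q_range = (float(q[valid].min()), float(q[valid].max()))
    edges = np.linspace(q_range[0], q_range[1], n_qbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def _binned(sel):
        qs = q[sel]
        ws = frame[sel]
        num, _ = np.histogram(qs, bins=edges, weights=ws)
        den, _ = np.histogram(qs, bins=edges)
        with np.errstate(invalid="ignore"):
            avg = np.where(den > 0, num / np.maximum(den, 1), 0.0)
        return avg

    profiles = [Profile1D(centers, _binned(valid & (seg == s)), segment=s)
                for s in range(n_segments)]
    average = Profile1D(centers, _binned(valid))
    return profiles, average


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass
class ClassificationResult:
    """Least-correlated representative profiles and the pixel labelling.

    Components are ordered by integrated (smoothed) intensity ascending,
    so component 0 is the weakest — in scans of tissue this is the
    background family.
    """

    components: np.ndarray            # (n_components, n_q)
    labels: np.ndarray                # per input profile
    representative_indices: np.ndarray
    q_nm: np.ndarray
    q_range: tuple[float, float]
    smooth_window: int
    flags: list[str] = field(default_factory=list)


def _boxcar(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    return np.apply_along_axis(
        lambda row: np.convolve(row, kernel, mode="same"), -1, x)


def classify_profiles(profiles: np.ndarray, q_nm: np.ndarray,
                      n_components: int,
                      q_range: tuple[float, float] = (5.75, 34.4),
                      smooth_window: int = 4,
                      correlation_threshold: float | None = None) -> ClassificationResult:
    """Greedy least-correlated-profile classification.

    After boxcar smoothing over ``smooth_window`` samples and restriction
    to ``q_range``, the first representative is the profile of highest
    intensity variance; each further representative minimizes the maximum
    absolute Pearson correlation with those already selected.  Every
    profile is then assigned to the representative it correlates with
    most.  Deterministic: ties break to the lowest profile index.
    """
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[0] < 1:
        raise ValueError("need a (n_profiles, n_q) array")
    q_nm = np.asarray(q_nm, dtype=float)
    sel = (q_nm >= q_range[0]) & (q_nm <= q_range[1])
    if not sel.any():
        raise ValueError("q_range outside the profile grid")
    sm = _boxcar(profiles, smooth_window)[:, sel]
    centered = sm - sm.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]

    flags: list[str] = []
    variance = centered.var(axis=1)
    chosen = [int(np.argmax(variance))]
    # drop duplicates from the candidate pool via correlation with chosen
    while len(chosen) < n_components:
        corr = np.abs(unit @ unit[chosen].T)       # (n, n_chosen)
        corr[norms == 0] = 1.0                     # flat profiles never lead
        maxcorr = corr.max(axis=1)
        maxcorr[chosen] = np.inf
        cand = int(np.argmin(maxcorr))
        if not np.isfinite(maxcorr[cand]) or maxcorr[cand] >= 1.0 - 1e-12:
            flags.append(f"only {len(chosen)} distinct components found")
            break
        if correlation_threshold is not None and maxcorr[cand] > correlation_threshold:
            flags.append("correlation threshold reached")
            break
        chosen.append(cand)

    # order components by integrated smoothed intensity (background first)
    totals = sm[chosen].sum(axis=1)
    order = np.argsort(totals, kind="stable")
    chosen = [chosen[i] for i in order]
    reps_unit = unit[chosen]
    corr_to_reps = unit @ reps_unit.T
    corr_to_reps[norms == 0] = 0.0
    # flat (zero-variance) profiles correlate with nothing; send them to
    # the weakest component
    labels = np.where(norms > 0, np.argmax(corr_to_reps, axis=1), 0)
    return ClassificationResult(profiles[chosen], labels.astype(int),
                                np.array(chosen), q_nm, q_range,
                                smooth_window, flags)


# ---------------------------------------------------------------------------
# Collagen D-spacing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DSpacingResult:
    """Axial collagen period from equally spaced SAXS orders."""

    d_nm: float
    sigma_nm: float
    orders: tuple[int, ...]
    q_peaks_nm: tuple[float, ...]

    def __float__(self) -> float:
        return self.d_nm


def collagen_d_spacing(profile: Profile1D, max_order: int = 8,
                       prominence: float | None = None) -> DSpacingResult:
    """Fit detected SAXS peak positions to q_n = 2 pi n / D.

    Orders are assigned from the median spacing of consecutive peaks, and
    D follows from an intensity-weighted regression through the origin.
    At least two detected orders are required; missing intermediate
    orders are tolerated.
    """
    y = profile.intensity
    if prominence is None:
        prominence = 0.05 * float(y.max() - y.min())
    idx, props = find_peaks(y, prominence=prominence)
    if len(idx) < 2:
        raise ValueError("fewer than two collagen orders detected")
    qp = profile.q_nm[idx]
    heights = y[idx]
    dq = float(np.median(np.diff(qp))) if len(qp) > 1 else float(qp[0])
    n = np.maximum(np.round(qp / dq).astype(int), 1)
    if len(np.unique(n)) < 2:
        raise ValueError("fewer than two distinct orders detected")
    # weighted least squares through the origin: q = (2 pi / D) n
    w = heights
    slope = float(np.sum(w * n * qp) / np.sum(w * n * n))
    d_nm = 2.0 * math.pi / slope
    resid = qp - slope * n
    dof = max(len(qp) - 1, 1)
    var_slope = float(np.sum(w * resid**2) / dof / np.sum(w * n * n))
    sigma = 2.0 * math.pi / slope**2 * math.sqrt(max(var_slope, 0.0))
    keep = idx[: max_order] if max_order else idx
    return DSpacingResult(d_nm, sigma, tuple(int(v) for v in n),
                          tuple(float(v) for v in qp))
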