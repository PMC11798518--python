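# Methods

This note records the models, defaults and design choices behind
`mcspec`, and what the synthetic phantoms do and do not demonstrate.

## X-ray physics (`mcspec.physics`)

Mass attenuation coefficients ship as a pinned CSV tabulation
(`data/attenuation_cl.csv`) of photoabsorption cross sections computed
from Cromer–Liberman anomalous scattering factors, on a geometric grid
from 0.2 to 25 keV with extra points bracketing every absorption edge.
Lookups interpolate log-log, which reproduces grid points exactly and is
monotone between them. Coherent/incoherent scattering is not included;
below ~10 keV it contributes at most a few percent for these light
matrices. Hydrogen, absent from the Cromer–Liberman data and a
negligible absorber here, carries a short hand-pinned curve.

Matrices are defined by stoichiometry and density: hydroxyapatite
Ca₁₀(PO₄)₆(OH)₂ at 3.16 g cm⁻³, whitlockite Ca₉Mg(PO₄)₆(HPO₄) at 3.12,
A- and B-type carbonated apatites, calcite, monohydrate amorphous
calcium carbonate (nominal 2.0 g cm⁻³) and embedding paraffin. Each
matrix additionally carries *reference* mass fractions — the theoretical
constants quantification is pinned to (w_Ca = 0.39, w_P = 0.196 for HAP;
0.182/0.169 for the A/B carbonated forms; w_Mg = 0.023, w_P = 0.184 for
whitlockite). Where a reference constant and the stoichiometric value
disagree (the carbonated stoichiometries behind some constants are not
uniquely determined), the registry constant is authoritative for
quantification and the stoichiometric value is reported as an advisory
with a consistency flag. Emission-line energies in fits are
full-precision tabulated values; the rounded values seen in figure
legends are display metadata only.

A caveat worth knowing: with this tabulation the 1/e length of
stoichiometric HAP at the Ca Kα energy (3.69 keV) evaluates to ≈14 µm.
Quoted probing depths for carbonated-apatite matrices can be longer
(≈18 µm), depending on the assumed stoichiometry and density; the
package always reports what its own pinned tabulation and the stated
matrix give.

## XRF quantification (`mcspec.xrf`)

*Thickness.* t_eff = −ln(I/I₀)·δ(matrix, E_in), in µm. Transmission
noise above unity is clipped to t = 0 and counted; non-positive
intensities are flagged invalid. Thickness for the fit constraint is
taken from the 2.5 keV scan also when fitting the 2.1/4.2 keV cubes
(the cubes must be co-registered on the same grid; registration itself
is out of scope). Map products are masked below 0.5 µm effective
thickness, with 0.3/0.5/1.0 µm isolines drawn on renderings — outside
the deposit the matrix assumption fails and matrix-referenced fractions
are meaningless.

*Forward model.* Per line: photoabsorption coefficient of the element at
E_in × a fixed shell share of the edge jump (0.85 for K, 0.45/0.35 for
L3/L2) × fluorescence yield × branching fraction × self-absorption
A(t) for the 84°/6° beam/detector geometry. Detector response is
Gaussian with FWHM² = noise² + k·E anchored at 150 eV at 5.9 keV (the
Mn Kα convention; the anchor energy for the quoted 150 eV resolution is
a convention choice). Every line carries an escape satellite at
E − 1.742 keV with a default escape fraction of 1.5 % (configurable; the
escape magnitude of the real detector is not published). An elastic peak
sits at E_in. No Compton continuum, secondary fluorescence or pile-up.

*Fit.* Non-negative least squares on per-element templates (fixed line
positions, no per-pixel energy recalibration) after background
subtraction. The default background is a SNIP-style iterative
low-clipping estimate in the compressed log-log-sqrt domain, window 24
channels — parameter-light and standard for energy-dispersive spectra;
the fit also accepts a fixed vector or none. Reference-element areas
≤ 0 flag the pixel unquantifiable; the reference element's output
fraction equals the registry constant bit-exactly by construction.
Noise-free, fit∘simulate is the identity to better than 1e−6 relative.

*Geometry as a systematic.* The detector is treated as a point at exit
angle β = 6°; the finite 6–10° opening is explored by re-fitting over a
β range (`exit_angle_sensitivity`) rather than by solid-angle
integration, mirroring how geometry uncertainty propagates into the
thickness-binned comparisons.

*Binning.* Spectra are grouped by effective thickness, averaged, and the
average fitted once per bin at the bin-mean thickness. Within-bin
thickness spread introduces a small systematic (the self-absorption
factor is averaged nonlinearly); with the default bin edges this stays
at the few-percent level and is shared between samples compared in the
same bins.

## XANES (`mcspec.xanes`)

Normalization subtracts a linear pre-edge fit and scales the post-edge
step (post-edge line extrapolated to the maximum-derivative edge
position) to one; optional flattening. The operation is idempotent and
affine-invariant; ranges must bracket the edge or a `ValueError` names
the conflict.

No measured reference spectra are bundled. The parametric generator
builds the six references (HAP, HAP A, HAP B, WHIT, calcite, ACC) from
an arctangent edge, a Gaussian white line, a ~4060 eV shoulder and
damped post-edge cosine oscillations, with the discriminating features
placed per the known contrast: apatite white line at 4048.6 eV versus
whitlockite at 4049.5 eV, and the 4060 eV shoulder present only in the
apatites; the three apatite variants differ only mildly (white-line
amplitude/width, shoulder height), which makes their individual weights
ill-conditioned on purpose — grouped quantities (tot HAP) are the robust
observables. Vaterite and aragonite are deliberately not part of the
fitting library. Measured references drop in as two-column files.

LCF solves non-negative least squares; with the sum-to-one constraint
(default on — the constraint convention is a documented choice, both
modes are supported) a soft constraint row is added and the weights are
renormalized exactly afterwards. No energy shift is fitted between
sample and references; a cross-correlation shift is reported as a
diagnostic only. Fluorescence-yield spectra are not over-absorption
corrected; the detection-mode tag propagates to the output as a caveat.
Line scans apply the 0.5 µm effective-thickness filter before fitting.

## WAXS (`mcspec.waxs`)

Peak positions follow the hexagonal-setting metric
1/d² = (4/3)(h²+hk+k²)/a² + l²/c², with the obverse rhombohedral
condition −h+k+l = 3n applied to all symmetry equivalents for
whitlockite so a powder line survives if any equivalent is allowed.

Refinement is a deliberate simplification of full Rietveld: free
per-reflection intensities (no structure factors) and a two-direction
anisotropic width model, 1/D(hkl) = cos²φ/D₀₀₂ + sin²φ/D₁₁₀ with φ the
angle of the scattering vector to c* — the minimum model that returns
the quantities of interest (cell plus domain sizes along [002] and
[110]). Spherical-harmonics broadening is out of scope. Peak shape is
pseudo-Voigt with fixed η = 0.5 (configurable); the background is
interpolated through anchor q points and never refined; an instrumental
resolution width (from a standard-powder calibration, supplied as
configuration) is added in quadrature inside the model and therefore
deconvolved from the refined sizes. The Scherrer constant is fixed at
K = 0.9; in q-space the Scherrer relation is the angle-free
β_q = 2πK/D, so the width→size→width loop closes to machine precision
and all size claims are internally consistent under the single fixed K.

Numerically, intensities are profiled out by NNLS at every step
(variable projection); reflections up to 2 nm⁻¹ outside the fit window
stay in the basis because their tails leak in; a coarse grid scan over
global a- and c-scale factors precedes the local trust-region solve
because the free-intensity landscape has shallow false valleys for
densely overlapping patterns (neighbouring intensities partly absorb a
wrong cell); the local solve uses central differences with Jacobian
scaling. Noise-free, refine∘synthesize is the identity across cells ±2 %
and domains 40–300 Å.

Classification is a greedy least-correlated variant (the published
algorithm's exact update rules live in an external reference): boxcar
smoothing (default window 4 samples), restriction to q = 5.75–34.4 nm⁻¹,
first representative by maximum variance, subsequent ones minimizing the
maximum absolute correlation with those already chosen, assignment by
maximum correlation. Components are ordered by integrated intensity so
component 0 is the weakest (background); flat profiles are assigned
there. The labelling is deterministic and permutation-invariant as a
partition. The small smoothing window is what keeps low-intensity,
narrow-peaked phases (whitlockite) detectable; a window-4-versus-10
comparison is exposed as a diagnostic in the tests.

Azimuthal integration is plain histogram binning of q = (4π/λ)sin θ in
16 azimuthal wedges — adequate for the synthetic frames and generic ring
calibrations; no polarization or solid-angle corrections. Collagen
D-spacing assigns order numbers from the median peak spacing and
regresses q_n = 2πn/D through the origin with intensity weights,
tolerating missing orders. The per-pixel "abundance" of a component is
its integrated background-subtracted peak intensity.

## Phantoms (`mcspec.phantom`)

Scenes are 64×64 by default (48×48 in the pipeline, 32×32 in tests — the
same contracts at smaller raster sizes), 2 µm pixels: an elliptical
deposit core of 3–5 µm effective thickness with a smooth radial relief
and 3 % thickness roughness, a 0.5–1 µm periphery, and for the benign
preset a rim ring carrying whitlockite (with Mg approaching its 2.3 %
theoretical fraction) and an elevated amorphous-carbonate share. DCIS
carries high-crystallinity apatite (domains 244/129 Å) and a patchy Mg
field peaking near 0.03; IDC the lowest Mg and the highest Na; the
benign core is low-crystallinity apatite (96/53 Å). Traces sit in the
reported ranges (Na 0.005–0.02, S 0.001–0.01, Cl 0.002–0.004, Y > Sr).
Carbonate admixture rises toward thin regions, which produces the
positive w_P-versus-thickness trend the dilution model inverts.

Mixed-matrix pixels are rendered layer-homogeneous (one effective
attenuation coefficient); stratified layering is out of scope. Counting
noise is Poisson; transmission noise optional multiplicative Gaussian;
every renderer is deterministic under its seed. The XRF counts scale
defaults to 5000 (incident-flux × live-time units), chosen so a deposit
pixel collects a few 10⁴ counts in the dominant line over a 6 s dwell —
the absolute count rate of a real scan is instrument-specific and stays
a free parameter.

What passing phantom tests shows: the analysis chain is internally
consistent (each fit inverts its forward model), the matrix-referencing
conventions behave as documented, and the three modalities agree on a
constructed rim. What it cannot show: correctness of the physics
tabulations against a given instrument, real detector artefacts beyond
the modelled escape peaks, surface roughness and geometry errors,
organic-matrix fluorescence backgrounds, or anything about real tissue.

## Pipeline

`run_all` executes thickness → XRF maps/bins → XANES line scan → WAXS
classification/refinement, writes CSV/TIFF/PNG products plus a JSON
summary with rounded floats and sorted keys (byte-identical under the
same seed), and logs every decided default. The rim flags demand
margins, not bare inequalities: the XANES rim call requires the rim
whitlockite share to exceed the core share by 0.1, and the WAXS call
requires >80 % of whitlockite-labelled pixels inside the rim/periphery.
Stage failures leave a partial bundle and a non-zero exit.
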