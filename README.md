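# mcspec

Quantitative multi-modal X-ray analysis of tissue microcalcifications.

Microcalcifications (MC) — micrometre-scale mineral deposits found in
breast biopsies — are analysed at synchrotron microprobes with three
co-registered raster-scan modalities. `mcspec` implements the full
analysis chain for all three, plus a synthetic phantom generator that
renders benign / DCIS / IDC-like scenes into every modality from one
ground-truth description, so the whole pipeline is testable end to end
without measured data.

**Who it is for:** beamline users and analysts working with scanning
XRF/XANES/WAXS data of thin calcified sections who need reproducible,
scriptable quantification rather than interactive GUI fits.

## The methods

**Thickness-constrained XRF quantification.** The transmission map
recorded alongside each fluorescence scan is inverted by Beer–Lambert,
t_eff = −ln(I/I₀)·δ(E), into an *effective matrix thickness* assuming a
fixed mineral matrix (carbonated apatite, HAP type B, by default). Each
pixel's spectrum is then fitted with a forward model — tabulated line
energies, per-line self-absorption
A(t) = (1−e^(−χρt))/(χρt), χ = μ/ρ(E_in)/sin α + μ/ρ(E_line)/sin β,
Gaussian detector response with silicon escape satellites at
E − 1.742 keV, an elastic peak — with that pixel's thickness as a fixed
constraint. Mass fractions are matrix-referenced:
w_Z = (A_Z/S_Z)/(A_ref/S_ref)·w_ref, with the reference element (Ca at
4.2 keV, P at 2.5 keV, O at 2.1 keV) pinned to its theoretical fraction.
Sr and Y, measurable only below the P edge, are rescaled onto the
P-referenced scale via w(Z) = w(Z, 2.1 keV)·w(Mg, 2.5 keV)/w(Mg, 2.1 keV).
Spectra can also be pooled into effective-thickness bins and fitted once
per bin, and the linear trend of w_P with thickness inverted as a
dilution by P-free, Ca-bearing species, x_P,eff = (1−α)·x_P,HAP.

**Ca K-edge XANES linear-combination fitting.** Spectra are edge-step
normalized (linear pre-edge subtracted, post-edge step scaled to one) and
decomposed as non-negative weighted sums of reference spectra
(hydroxyapatite and its A/B carbonated variants, whitlockite, calcite,
amorphous calcium carbonate). The apatite white line sits at
~4048.6 eV, whitlockite's at ~4049.5 eV. Species are grouped as
tot HAP = HAP + HAP A + HAP B and
WHIT share = WHIT/(WHIT + tot HAP), the whitlockite fraction of the
calcium phosphates.

**WAXS profile analysis.** 2D frames are azimuthally integrated into
I(q) (q = 4π sin θ/λ); raster scans are classified into least-correlated
representative profiles; whole patterns are refined with free peak
intensities to recover the hexagonal apatite and rhombohedral
whitlockite cells plus anisotropic crystalline domain sizes through the
q-space Scherrer relation β_q = 2πK/D. Collagen D-spacing comes from
equally spaced SAXS orders q_n = 2πn/D.

## Worked example

Refine a synthetic noise-free apatite pattern from a +1 % perturbed
start:

```python
import numpy as np
from dataclasses import replace
from mcspec.waxs import HAP_PHASE, Profile1D, refine_profile, synthesize_profile

q = np.linspace(6.0, 34.4, 800)          # nm^-1
y = synthesize_profile(q, HAP_PHASE)
start = replace(HAP_PHASE, a=HAP_PHASE.a * 1.01, c=HAP_PHASE.c * 1.01)
print(refine_profile(Profile1D(q, y), start).summary())
```

```
whole-pattern refinement
==============================================
HAP        a =    9.3897 Å  c =    6.8652 Å  D[002] =  244.0 Å  D[110] =  129.0 Å
cost = 1.4619e-27  converged = True  (12 evaluations)
```

The refinement recovers the generating cell (a = 9.3897 Å,
c = 6.8652 Å) to four decimals and the domain sizes (244 Å along [002],
129 Å along [110]) exactly — the free-intensity whole-pattern fit is an
exact inverse of the generator on noise-free input.

Attenuation lengths of stoichiometric hydroxyapatite (ρ = 3.16 g cm⁻³)
from the shipped tabulation:

```python
from mcspec import physics as P
hap = P.get_matrix("HAP")
for e in (2.1, 2.5, 1.25, 3.69):
    print(f"delta(HAP, {e} keV) = {P.attenuation_length(hap, e):.2f} um")
```

```
delta(HAP, 2.1 keV) = 5.74 um
delta(HAP, 2.5 keV) = 4.92 um
delta(HAP, 1.25 keV) = 1.41 um
delta(HAP, 3.69 keV) = 14.21 um
```

The probing depth at the mapping energies is ~5 µm while the Mg Kα
fluorescence escapes from only ~1.4 µm — the reason the per-pixel
thickness constraint matters.

An end-to-end phantom run from the shell:

```bash
mcspec all --preset benign --seed 2 --out run_benign
# summary flags: {'rim_Mg_enhanced': True, 'whit_rim_xanes': True,
#                 'whit_rim_waxs': True, 'whit_rim': True}
```

On the benign preset all three modalities agree on the rim: the Mg mass
fraction rises toward thin bins, the XANES whitlockite share is higher
in the rim than the core, and the classified whitlockite WAXS component
is confined to the rim ring.

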