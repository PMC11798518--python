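"""XRF quantification: thickness inversion, forward model, fits, binning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mcspec import physics as P
from mcspec.xrf import (
    DetectorModel,
    GeometryModel,
    SpectrumCube,
    ThicknessMap,
    bin_by_thickness,
    carbonate_dilution_model,
    effective_thickness_map,
    fit_cube,
    fit_spectrum,
    rescale_trace_fractions,
    self_absorption_factor,
    simulate_spectrum,
    snip_background,
)


def make_cube(trans, e_in=2.5, n_channels=64):
    trans = np.asarray(trans, dtype=float)
    counts = np.zeros(trans.shape + (n_channels,))
    return SpectrumCube(counts, e_in, 0.005, transmission=trans, i0=1.0)


class TestEffectiveThickness:
    def test_full_transmission_is_zero(self, hap_b):
        tm = effective_thickness_map(make_cube([[1.0]]), hap_b)
        assert tm.t_um[0, 0] == 0.0

    def test_one_over_e_gives_attenuation_length(self, hap):
        tm = effective_thickness_map(make_cube([[np.exp(-1.0)]]), hap)
        assert tm.t_um[0, 0] == pytest.approx(
            P.attenuation_length(hap, 2.5), rel=1e-12)

    def test_noisy_transmission_clipped_and_counted(self, hap_b):
        tm = effective_thickness_map(make_cube([[1.02, 0.5]]), hap_b)
        assert tm.t_um[0, 0] == 0.0
        assert tm.n_clipped == 1

    def test_nonpositive_intensity_flagged_invalid(self, hap_b):
        tm = effective_thickness_map(make_cube([[0.0, 0.5]]), hap_b)
        assert np.isnan(tm.t_um[0, 0])
        assert tm.invalid[0, 0]
        assert not tm.mask(0.0)[0, 0]


class TestSelfAbsorption:
    def test_zero_thickness_limit(self, hap_b, geom):
        assert self_absorption_factor(0.0, hap_b, 4.2, 3.6917, geom) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.floats(min_value=0.01, max_value=30.0),
           st.floats(min_value=1.05, max_value=3.0))
    def test_monotone_decreasing_in_thickness(self, t, factor):
        m = P.get_matrix("HAP_B")
        g = GeometryModel()
        a1 = self_absorption_factor(t, m, 4.2, 3.6917, g)
        a2 = self_absorption_factor(t * factor, m, 4.2, 3.6917, g)
        assert 0.0 < a2 < a1 <= 1.0

    def test_matches_quadrature_oracle(self, hap_b, geom):
        # A(t) must equal the depth-average of the two-path attenuation
        from scipy.integrate import quad
        t_um, e_in, e_line = 5.0, 4.2, 3.6917
        chi = (P.mass_attenuation(hap_b, e_in) / np.sin(np.radians(geom.alpha_deg))
               + P.mass_attenuation(hap_b, e_line) / np.sin(np.radians(geom.beta_deg)))
        rho = hap_b.density
        t_cm = t_um * 1e-4
        oracle, _ = quad(lambda z: np.exp(-chi * rho * z), 0.0, t_cm)
        oracle /= t_cm
        got = self_absorption_factor(t_um, hap_b, e_in, e_line, geom)
        assert got == pytest.approx(oracle, abs=1e-10)


class TestForwardModel:
    def test_calcium_not_excited_below_edge(self, hap_b, det, geom):
        spec = simulate_spectrum({"Ca": 1.0}, 4.0, hap_b, 2.5, det, geom)
        energies = det.channel_energies()
        # all intensity must sit at the elastic peak, none at Ca Ka
        ca_window = np.abs(energies - 3.6917) < 0.15
        elastic_window = np.abs(energies - 2.5) < 0.15
        # nothing at Ca Ka beyond the underflowing elastic tail
        assert spec[ca_window].max() < 1e-20 * spec[elastic_window].max()
        assert spec[elastic_window].sum() > 0.0

    def test_escape_peak_position(self, hap_b, geom):
        det = DetectorModel(n_channels=1024)
        spec = simulate_spectrum({"Ca": 0.39, "O": 0.61}, 4.0, hap_b, 4.2,
                                 det, geom)
        energies = det.channel_energies()
        esc_window = np.abs(energies - (3.6917 - 1.742)) < 0.06
        assert spec[esc_window].max() > 0.0
        noesc = simulate_spectrum(
            {"Ca": 0.39, "O": 0.61}, 4.0, hap_b, 4.2,
            DetectorModel(escape_fraction=0.0), geom)
        assert noesc[esc_window].max() < spec[esc_window].max()

    def test_forward_model_linear_in_fraction(self, hap_b, det, geom):
        base = {"P": 0.169, "Mg": 0.01}
        double = {"P": 0.169, "Mg": 0.02}
        s1 = simulate_spectrum(base, 4.0, hap_b, 2.5, det, geom)
        s2 = simulate_spectrum(double, 4.0, hap_b, 2.5, det, geom)
        energies = det.channel_energies()
        mg = np.abs(energies - 1.2536) < 0.05
        elastic_and_p = ~mg
        mg_only_1 = s1[mg] - simulate_spectrum({"P": 0.169}, 4.0, hap_b, 2.5,
                                               det, geom)[mg]
        mg_only_2 = s2[mg] - simulate_spectrum({"P": 0.169}, 4.0, hap_b, 2.5,
                                               det, geom)[mg]
        assert np.allclose(mg_only_2, 2.0 * mg_only_1, rtol=1e-12)


class TestFitSimulateIdentity:
    @pytest.mark.parametrize("e_in,extra", [
        (2.1, {"Na": 0.01, "Mg": 0.015, "Si": 0.002, "Sr": 0.0004, "Y": 0.0008}),
        (2.5, {"Na": 0.01, "Mg": 0.015, "Si": 0.002, "P": 0.169, "S": 0.004}),
        (4.2, {"Na": 0.01, "Mg": 0.015, "P": 0.169, "S": 0.004, "Cl": 0.003,
               "Ca": 0.39}),
    ])
    def test_noise_free_round_trip(self, e_in, extra, hap_b, det, geom):
        """The module's master oracle: fit(simulate(w)) == w to 1e-6."""
        from mcspec.xrf import reference_element_for
        ref = reference_element_for(e_in)
        w = dict(extra)
        w.setdefault("O", float(P.theoretical_mass_fraction(hap_b, "O")))
        w[ref] = float(P.theoretical_mass_fraction(hap_b, ref))
        spec = simulate_spectrum(w, 3.5, hap_b, e_in, det, geom,
                                 counts_scale=1e4)
        res = fit_spectrum(spec, e_in, 3.5, hap_b, det, geom,
                           background="none")
        assert not res.unquantifiable
        assert res.mass_fractions[ref] == res.reference_value  # bit-exact
        for el, true in w.items():
            if el == ref or el not in res.mass_fractions:
                continue
            assert res.mass_fractions[el] == pytest.approx(true, rel=1e-6), el

    def test_all_zero_spectrum_unquantifiable(self, hap_b, det, geom):
        res = fit_spectrum(np.zeros(det.n_channels), 2.5, 3.0, hap_b, det, geom,
                           background="none")
        assert res.unquantifiable

    def test_poisson_mg_recovery_within_20_percent(self, hap_b, det, geom):
        """Trace Mg at the percent level survives counting noise."""
        rng = np.random.default_rng(11)
        w = {"P": 0.169, "O": 0.55, "Mg": 0.01}
        spec = simulate_spectrum(w, 4.0, hap_b, 2.5, det, geom,
                                 counts_scale=5000.0, poisson=True, rng=rng)
        res = fit_spectrum(spec, 2.5, 4.0, hap_b, det, geom)
        assert res.mass_fractions["Mg"] == pytest.approx(0.01, rel=0.2)

    def test_omitting_escape_model_biases_p_and_s_high(self, hap_b, geom):
        """Ca escape lines overlap P/S: ignoring them inflates both."""
        det = DetectorModel(escape_fraction=0.015)
        blind = DetectorModel(escape_fraction=0.0)
        w = {"Ca": 0.39, "P": 0.169, "S": 0.003, "O": 0.42}
        spec = simulate_spectrum(w, 4.0, hap_b, 4.2, det, geom,
                                 counts_scale=1e5)
        good = fit_spectrum(spec, 4.2, 4.0, hap_b, det, geom, background="none")
        bad = fit_spectrum(spec, 4.2, 4.0, hap_b, blind, geom, background="none")
        assert good.mass_fractions["S"] == pytest.approx(0.003, rel=1e-4)
        assert bad.mass_fractions["S"] > good.mass_fractions["S"]
        assert bad.mass_fractions["P"] > good.mass_fractions["P"]

    def test_multi_energy_mg_consistency(self, hap_b, det, geom):
        """Mg referenced via O (2.1 keV) and via P (2.5 keV) agree."""
        comp = {el: w * 0.975 for el, w in hap_b.composition.items()}
        comp["Mg"] = 0.015
        comp["Na"] = 0.01
        out = {}
        for e_in in (2.1, 2.5):
            spec = simulate_spectrum(comp, 4.0, hap_b, e_in, det, geom,
                                     counts_scale=1e4)
            res = fit_spectrum(spec, e_in, 4.0, hap_b, det, geom,
                               background="none")
            out[e_in] = res.mass_fractions["Mg"]
        assert out[2.1] == pytest.approx(out[2.5], rel=0.05)


class TestSnip:
    def test_flat_background_recovered(self):
        y = np.full(256, 50.0)
        bg = snip_background(y)
        assert np.allclose(bg, 50.0, rtol=0.02)

    def test_peak_removed_from_estimate(self):
        x = np.arange(256, dtype=float)
        y = 20.0 + 500.0 * np.exp(-0.5 * ((x - 128) / 4.0) ** 2)
        bg = snip_background(y)
        assert bg[128] < 60.0


class TestCubeFit:
    def _uniform_cube(self, hap_b, det, geom, shape=(4, 4), noise=False, seed=5):
        rng = np.random.default_rng(seed)
        w = {"P": 0.169, "O": 0.55, "Mg": 0.012}
        t = np.full(shape, 3.5)
        counts = np.empty(shape + (det.n_channels,))
        for r in range(shape[0]):
            for c in range(shape[1]):
                counts[r, c] = simulate_spectrum(
                    w, t[r, c], hap_b, 2.5, det, geom, counts_scale=5000.0,
                    poisson=noise, rng=rng)
        cube = SpectrumCube(counts, 2.5, det.gain_kev, live_time_s=6.0)
        return cube, ThicknessMap(t, hap_b.name, 2.5), w

    def test_uniform_phantom_gives_constant_maps(self, hap_b, det, geom):
        cube, tmap, w = self._uniform_cube(hap_b, det, geom, noise=True)
        out = fit_cube(cube, tmap, hap_b, det, geom, background="none")
        mg = out.fractions["Mg"]
        assert np.all(np.isfinite(mg))
        assert np.std(mg) / np.mean(mg) < 0.1
        assert np.mean(mg) == pytest.approx(0.012, rel=0.1)

    def test_fully_thin_map_is_fully_masked(self, hap_b, det, geom):
        cube, tmap, _ = self._uniform_cube(hap_b, det, geom)
        thin = ThicknessMap(np.full(cube.shape, 0.2), hap_b.name, 2.5)
        out = fit_cube(cube, thin, hap_b, det, geom, background="none")
        assert np.all(np.isnan(out.fractions["Mg"]))
        # masked pixels are NaN sentinels, never zero
        assert not np.any(out.fractions["Mg"] == 0.0)

    def test_misregistered_inputs_rejected(self, hap_b, det, geom):
        cube, _, _ = self._uniform_cube(hap_b, det, geom)
        bad = ThicknessMap(np.full((3, 3), 2.0), hap_b.name, 2.5)
        with pytest.raises(ValueError):
            fit_cube(cube, bad, hap_b, det, geom)


class TestRescale:
    def test_printed_formula_arithmetic(self):
        w21 = {"Sr": np.array([[0.002]]), "Mg": np.array([[0.02]])}
        out = rescale_trace_fractions(w21, np.array([[0.01]]))
        assert out["Sr"][0, 0] == pytest.approx(0.001)

    def test_identity_when_mg_maps_agree(self):
        w21 = {"Sr": np.array([[0.002]]), "Y": np.array([[0.004]]),
               "Mg": np.array([[0.015]])}
        out = rescale_trace_fractions(w21, np.array([[0.015]]))
        assert out["Sr"][0, 0] == pytest.approx(0.002)
        assert out["Y"][0, 0] == pytest.approx(0.004)

    def test_sr_y_ratio_invariant_and_zero_mg_masked(self):
        w21 = {"Sr": np.array([[0.002, 0.003]]), "Y": np.array([[0.004, 0.006]]),
               "Mg": np.array([[0.02, 0.0]])}
        out = rescale_trace_fractions(w21, np.array([[0.01, 0.01]]))
        assert out["Sr"][0, 0] / out["Y"][0, 0] == pytest.approx(0.5)
        assert np.isnan(out["Sr"][0, 1])


class TestBinning:
    def _gradient_cube(self, hap_b, det, geom):
        # 1x6 scan with a thickness gradient, noise-free
        t = np.array([[0.6, 1.2, 2.0, 2.8, 3.6, 4.4]])
        w = {"P": 0.169, "O": 0.55, "Mg": 0.012}
        counts = np.empty((1, 6, det.n_channels))
        for c in range(6):
            counts[0, c] = simulate_spectrum(w, t[0, c], hap_b, 2.5, det, geom,
                                             counts_scale=5000.0)
        cube = SpectrumCube(counts, 2.5, det.gain_kev)
        return cube, ThicknessMap(t, hap_b.name, 2.5)

    def test_uniform_composition_gives_flat_curve(self, hap_b, det, geom):
        cube, tmap = self._gradient_cube(hap_b, det, geom)
        df = bin_by_thickness(cube, tmap, [0.5, 1.5, 3.0, 5.0], hap_b, det,
                              geom, background="none")
        assert len(df) == 3
        # flat to within the bin-averaging systematic (spectra averaged
        # over a bin are fitted at the bin-mean thickness)
        assert np.allclose(df["w_Mg"], 0.012, rtol=0.1)
        assert df["w_Mg"].std() / df["w_Mg"].mean() < 0.05

    def test_single_pixel_bins_match_per_pixel_fit(self, hap_b, det, geom):
        cube, tmap = self._gradient_cube(hap_b, det, geom)
        edges = [0.5, 0.9, 1.5, 2.4, 3.2, 4.0, 5.0]
        df = bin_by_thickness(cube, tmap, edges, hap_b, det, geom,
                              background="none")
        assert (df["n_pixels"] == 1).all()
        res = fit_spectrum(cube.counts[0, 0], 2.5, tmap.t_um[0, 0], hap_b,
                           det, geom, background="none")
        assert df.iloc[0]["w_Mg"] == pytest.approx(
            res.mass_fractions["Mg"], rel=1e-12)

    def test_empty_bins_dropped(self, hap_b, det, geom):
        cube, tmap = self._gradient_cube(hap_b, det, geom)
        df = bin_by_thickness(cube, tmap, [0.5, 0.55, 3.0, 5.0], hap_b, det,
                              geom, background="none")
        assert len(df) == 2   # the sliver bin holds nothing


class TestCarbonateDilution:
    def _table(self, alphas, ts, w_ref=0.169):
        import pandas as pd
        return pd.DataFrame({
            "t_mean_um": ts,
            "w_P": [(1 - a) * w_ref for a in alphas],
        })

    def test_no_dilution_flat_at_reference(self):
        df = self._table([0.0] * 4, [1.0, 2.0, 3.0, 4.0])
        res = carbonate_dilution_model(df, w_p_reference=0.169)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.169)
        assert np.allclose(res.alpha, 0.0, atol=1e-12)

    def test_half_dilution(self):
        df = self._table([0.5] * 3, [1.0, 2.0, 3.0])
        res = carbonate_dilution_model(df, w_p_reference=0.169)
        assert np.allclose(res.alpha, 0.5, atol=1e-12)

    def test_linear_gradient_recovered(self):
        ts = np.linspace(0.5, 4.5, 6)
        alphas = 0.4 - 0.08 * ts          # alpha falls with thickness
        df = self._table(alphas, ts)
        res = carbonate_dilution_model(df, w_p_reference=0.169)
        # w_P = (1 - 0.4 + 0.08 t) w_ref -> slope = 0.08 * w_ref
        assert res.slope == pytest.approx(0.08 * 0.169, rel=1e-9)
        assert np.allclose(res.alpha, alphas, atol=1e-12)

    def test_degenerate_thickness_range_rejected(self):
        df = self._table([0.1, 0.1, 0.1], [2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            carbonate_dilution_model(df, w_p_reference=0.169)
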