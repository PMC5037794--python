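import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from silkconform import deconv, synth
from silkconform.deconv import (
    AlaCbetaModel,
    FitError,
    SaturationModel,
    default_cbeta_model,
    detect_silkI_carbonyl,
    fit_saturation,
    fractions_report,
)
from silkconform.spectra import Spectrum1D
from silkconform.synth import (
    CBETA_LABELS,
    SeriesModel,
    SpectrumParams,
    cbeta_components,
    synth_carbonyl_spectrum,
    synth_cbeta_spectrum,
    synth_series,
)


def _fit_fractions(fracs, **fit_kw):
    spec = synth_cbeta_spectrum(cbeta_components(fracs))
    return AlaCbetaModel(spec).fit(**fit_kw)


class TestDefaultModel:
    def test_invariants_hold(self):
        m = default_cbeta_model()
        by = {c.label: c for c in m.components}
        assert by["silkI*"].center == by["random_coil"].center == 16.5
        assert by["silkI*"].fwhm_max < by["random_coil"].fwhm_min
        assert by["beta_A"].center == 19.6 and by["beta_B"].center == 21.7

    def test_violating_width_gap_rejected(self):
        m = default_cbeta_model()
        comps = [c for c in m.components]
        comps[1] = deconv.ComponentBounds("silkI*", 16.5, 0.2, 50.0, 250.0)
        with pytest.raises(ValueError, match="width"):
            deconv.DeconvModelSpec(components=comps)


class TestFractionRecovery:
    @pytest.mark.parametrize("fracs", [
        (0.526, 0.299, 0.105, 0.070),  # glycerol-saturated film
        (0.616, 0.0, 0.230, 0.154),    # glycerol-free film
        (0.540, 0.300, 0.096, 0.064),
        (0.25, 0.25, 0.40, 0.10),      # arbitrary beta-heavy split
    ])
    def test_noise_free_round_trip_within_1e3(self, fracs):
        res = _fit_fractions(fracs)
        for lab, true in zip(CBETA_LABELS, fracs):
            assert res.fractions[lab] == pytest.approx(true, abs=1e-3)
        assert res.identifiable

    def test_pure_silkI_spectrum(self):
        res = _fit_fractions((0.0, 1.0, 0.0, 0.0))
        assert res.fractions["silkI*"] == pytest.approx(1.0, abs=1e-6)
        assert all(res.fractions[lab] <= 1e-6
                   for lab in ("random_coil", "beta_A", "beta_B"))

    def test_fractions_normalized(self):
        res = _fit_fractions((0.3, 0.3, 0.25, 0.15))
        assert sum(res.fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert (res.params["area"] >= 0).all()

    @given(hst.lists(hst.floats(min_value=0.05, max_value=1.0),
                     min_size=4, max_size=4))
    @settings(max_examples=8, deadline=None, derandomize=True)
    def test_round_trip_property_arbitrary_simplex(self, raw):
        fracs = tuple(np.asarray(raw) / np.sum(raw))
        res = _fit_fractions(fracs, n_starts=2)
        for lab, true in zip(CBETA_LABELS, fracs):
            assert res.fractions[lab] == pytest.approx(true, abs=1e-3)

    def test_width_and_center_recovery(self, film29_fractions):
        res = _fit_fractions(film29_fractions)
        assert res.component("silkI*")["fwhm_hz"] == pytest.approx(100.0,
                                                                   abs=5.0)
        assert res.component("random_coil")["fwhm_hz"] == pytest.approx(
            300.0, abs=5.0)
        assert res.component("beta_A")["center"] == pytest.approx(19.6,
                                                                  abs=0.02)

    def test_width_unit_contract(self, film29_fractions):
        # fitted fwhm reported in Hz equals fwhm in ppm times the frequency
        res = _fit_fractions(film29_fractions)
        spec = synth_cbeta_spectrum(cbeta_components(film29_fractions))
        model = AlaCbetaModel(spec)
        assert model.freq == spec.spectrometer_freq
        row = res.component("silkI*")
        fwhm_ppm = row["fwhm_hz"] / res.spectrometer_freq
        assert fwhm_ppm * res.spectrometer_freq == row["fwhm_hz"]

    def test_spectrum_not_covering_window_raises(self):
        spec = Spectrum1D(np.linspace(14, 20, 200), np.zeros(200))
        with pytest.raises(ValueError, match="window"):
            AlaCbetaModel(spec)


class TestIdentifiability:
    def test_equal_width_degeneracy_raises_flag(self):
        # generating both shared-center components at 300 Hz removes the
        # narrow/broad contrast the model relies on
        comps = cbeta_components(
            (0.5, 0.3, 0.12, 0.08),
            widths_hz={"random_coil": 200.0, "silkI*": 200.0})
        res = AlaCbetaModel(synth_cbeta_spectrum(comps)).fit()
        assert res.identifiability_flag

    def test_normal_cases_do_not_flag(self, film0_fractions):
        res0 = _fit_fractions(film0_fractions)
        res1 = _fit_fractions((0.0, 1.0, 0.0, 0.0))
        assert not res0.identifiability_flag
        assert not res1.identifiability_flag

    def test_flag_mentioned_in_summary(self):
        comps = cbeta_components(
            (0.5, 0.3, 0.12, 0.08),
            widths_hz={"random_coil": 200.0, "silkI*": 200.0})
        res = AlaCbetaModel(synth_cbeta_spectrum(comps)).fit()
        assert "not identifiable" in res.summary()


class TestNoiseResponse:
    def test_median_fraction_error_nondecreasing_in_noise(self,
                                                          film29_fractions):
        true = dict(zip(CBETA_LABELS, film29_fractions))
        medians = []
        for noise in (0.002, 0.02, 0.08):
            errs = []
            for seed in range(20):
                spec = synth_cbeta_spectrum(
                    cbeta_components(film29_fractions),
                    SpectrumParams(noise_sd=noise, seed=seed))
                res = AlaCbetaModel(spec).fit(n_starts=1)
                errs.append(max(abs(res.fractions[k] - true[k])
                                for k in CBETA_LABELS))
            medians.append(float(np.median(errs)))
        assert medians[0] <= medians[1] <= medians[2]


class TestCarbonylDetection:
    def test_marker_detected_with_center_and_width(self):
        det = detect_silkI_carbonyl(synth_carbonyl_spectrum(True))
        assert det.detected
        assert det.center == pytest.approx(177.0, abs=0.2)
        assert det.fwhm_hz <= 150.0
        assert det.improvement >= 0.20

    def test_broad_only_spectrum_not_detected(self):
        det = detect_silkI_carbonyl(synth_carbonyl_spectrum(False))
        assert not det.detected

    def test_zero_spectrum_not_detected(self):
        spec = Spectrum1D(np.linspace(165, 182, 400), np.zeros(400))
        det = detect_silkI_carbonyl(spec)
        assert not det.detected and det.center is None

    def test_region_not_covered_raises(self):
        spec = Spectrum1D(np.linspace(10, 30, 100), np.zeros(100))
        with pytest.raises(ValueError, match="carbonyl"):
            detect_silkI_carbonyl(spec)


class TestSaturation:
    def test_exact_curve_self_consistency(self):
        pts = [(c, min(c * 0.30 / 9, 0.30)) for c in (0, 3, 5, 9, 17, 29, 40)]
        res = fit_saturation(pts)
        assert res.plateau == pytest.approx(0.30, abs=1e-6)
        assert res.breakpoint == pytest.approx(9.0, abs=0.1)

    def test_all_zero_fractions_error(self):
        with pytest.raises(FitError, match="identifiable"):
            fit_saturation([(c, 0.0) for c in (0, 5, 9, 20)])

    def test_single_regime_error(self):
        # strictly rising, never saturating
        with pytest.raises(FitError, match="identifiable"):
            fit_saturation([(c, 0.01 * c) for c in (1, 2, 3, 4, 5, 6)])

    def test_noisy_series_plateau_within_002(self):
        rng = np.random.default_rng(7)
        concs = (0, 3, 5, 9, 17, 29, 40)
        plateaus = []
        for _ in range(20):
            pts = [(c, min(c * 0.30 / 9, 0.30) + rng.normal(0, 0.015))
                   for c in concs]
            plateaus.append(fit_saturation(pts).plateau)
        assert np.median(np.abs(np.array(plateaus) - 0.30)) < 0.02

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="4 points"):
            SaturationModel([0, 5, 9], [0, 0.1, 0.3])


class TestFractionsReport:
    def test_empty_input_gives_empty_table_with_header(self):
        rep = fractions_report([])
        assert len(rep.table) == 0
        assert "silkI*" in rep.table.columns
        assert rep.saturation is None

    def test_single_result_one_row(self, film29_fractions):
        res = _fit_fractions(film29_fractions)
        rep = fractions_report([(29.0, res)])
        assert len(rep.table) == 1
        assert rep.table.loc[0, "beta_total"] == pytest.approx(0.175,
                                                               abs=1e-3)

    def test_series_silkI_column_monotone_then_flat(self):
        concs = [0.0, 5.0, 9.0, 17.0, 29.0, 40.0, 50.0, 67.0]
        series = synth_series(SeriesModel(), concs)
        results = [(c, AlaCbetaModel(s).fit(n_starts=2)) for c, s in series]
        rep = fractions_report(results)
        silk = rep.table["silkI*"].to_numpy()
        rising = silk[rep.table["glyc_wt_percent"] <= 9.0]
        flat = silk[rep.table["glyc_wt_percent"] >= 9.0]
        assert np.all(np.diff(rising) >= -1e-6)
        assert np.all(np.abs(flat - 0.30) <= 0.011)
        assert rep.saturation is not None
        assert rep.saturation.plateau == pytest.approx(0.30, abs=0.01)
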