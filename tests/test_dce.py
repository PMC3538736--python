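"""DCE deconvolution chain."""

import numpy as np
import pytest

from renperf import synthetic
from renperf.asl import PerfusionMap
from renperf.dce import (
    AIF,
    ConcentrationCurve,
    DCESeries,
    RegularizationSpec,
    convolution_matrix,
    deconvolve,
    extract_aif,
    multislice_roi_mean,
    normalize_baseline,
    rbf_map,
    roi_concentration_curve,
    truncate_first_pass,
)
from renperf.synthetic import AIFModel, ResidueModel


def _flat_series(n_volumes=50, value=3.0, shape=(4, 4)):
    return DCESeries(
        volumes=np.full((*shape, n_volumes), value), dt=0.9, n_baseline=15
    )


class TestNormalizeBaseline:
    def test_constant_series_normalises_to_zero(self):
        out = normalize_baseline(_flat_series())
        assert np.all(out.volumes == 0)
        assert out.is_concentration

    def test_step_height_preserved(self):
        vol = np.full((2, 2, 50), 1.5)
        vol[..., 15:] += 0.25
        out = normalize_baseline(DCESeries(vol, dt=0.9, n_baseline=15))
        assert np.allclose(out.volumes[..., 15:], 0.25)
        assert np.allclose(out.volumes[..., :15], 0.0)

    def test_fifteen_baselines_leave_35_contrast_volumes(self):
        out = normalize_baseline(_flat_series(n_volumes=50))
        assert out.n_volumes - out.n_baseline == 35

    def test_baseline_must_leave_dynamics(self):
        with pytest.raises(ValueError, match="n_baseline"):
            DCESeries(np.zeros((2, 2, 15)), dt=0.9, n_baseline=15)


class TestTruncateFirstPass:
    def test_first_pass_of_long_series(self):
        out = truncate_first_pass(_flat_series(n_volumes=400), 50)
        assert out.n_volumes == 50

    def test_truncation_to_full_length_is_identity(self):
        series = _flat_series(n_volumes=60)
        out = truncate_first_pass(series, 60)
        np.testing.assert_array_equal(out.volumes, series.volumes)

    def test_sixty_volume_window(self):
        assert truncate_first_pass(_flat_series(n_volumes=400), 60).n_volumes == 60

    def test_window_must_keep_dynamics(self):
        with pytest.raises(ValueError, match="dynamics"):
            truncate_first_pass(_flat_series(), 16)


class TestExtractAIF:
    def test_single_pixel_roi_returns_that_curve(self):
        vol = np.zeros((3, 3, 20))
        vol[1, 1] = np.sin(np.arange(20)) + 2.0
        series = DCESeries(vol, dt=0.9, n_baseline=2)
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        aif = extract_aif(series, mask)
        np.testing.assert_array_equal(aif.curve.conc, vol[1, 1])

    def test_recovers_painted_gamma_variate(self, small_truth, noise_free_dce):
        norm = normalize_baseline(noise_free_dce)
        aif = extract_aif(norm, small_truth.aorta)
        model = AIFModel(t0=15 * 0.9)
        expected = synthetic.gamma_variate_aif(model, norm.times).curve.conc
        np.testing.assert_allclose(aif.curve.conc, expected, atol=1e-12)

    def test_peak_time_matches_calculus(self, small_truth, noise_free_dce):
        norm = normalize_baseline(noise_free_dce)
        aif = extract_aif(norm, small_truth.aorta)
        t_peak = aif.curve.times[np.argmax(aif.curve.conc)]
        assert abs(t_peak - (15 * 0.9 + 3.0 * 1.5)) <= 0.9 / 2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            extract_aif(_flat_series(), np.zeros((4, 4), bool))

    def test_bolus_free_curve_rejected(self):
        series = normalize_baseline(_flat_series())
        with pytest.raises(ValueError, match="bolus"):
            extract_aif(series, np.ones((4, 4), bool))


class TestDeconvolve:
    def _aif(self, n=50, dt=0.9):
        times = np.arange(n) * dt
        conc = synthetic.gamma_variate_aif(AIFModel(t0=2.0), times).curve.conc
        return ConcentrationCurve(times, conc)

    def test_unit_impulse_at_lag_one(self):
        ca = self._aif()
        ct = ConcentrationCurve(ca.times, np.roll(ca.conc, 1))
        h = deconvolve(ct, ca, RegularizationSpec(1e-12))
        assert np.argmax(h.h) == 1
        assert h.h[1] == pytest.approx(1 / 0.9, rel=1e-6)

    def test_zero_tissue_curve_gives_zero_response(self):
        ca = self._aif()
        ct = ConcentrationCurve(ca.times, np.zeros_like(ca.conc))
        h = deconvolve(ct, ca, RegularizationSpec(1e-12))
        np.testing.assert_allclose(h.h, 0.0, atol=1e-9)

    def test_noise_free_flow_recovery(self):
        """Exponential residue at known f: 6000 max(h) within 5% of f."""
        ca = self._aif()
        r = synthetic.residue_function(ResidueModel(), ca.times)
        f = 380.0
        ct_conc = (f / 6000.0) * 0.9 * np.convolve(ca.conc, r)[: len(ca.times)]
        h = deconvolve(ConcentrationCurve(ca.times, ct_conc), ca,
                       RegularizationSpec(1e-12))
        assert h.rbf == pytest.approx(f, rel=0.05)

    def test_reconvolution_residual_small(self):
        ca = self._aif()
        r = synthetic.residue_function(ResidueModel(), ca.times)
        ct_conc = (400 / 6000.0) * 0.9 * np.convolve(ca.conc, r)[: len(ca.times)]
        h = deconvolve(ConcentrationCurve(ca.times, ct_conc), ca,
                       RegularizationSpec(1e-12))
        a = convolution_matrix(ca.conc, 0.9)
        resid = np.linalg.norm(a @ h.h - ct_conc) / np.linalg.norm(ct_conc)
        assert resid <= 1e-6

    def test_common_delay_leaves_flow_unchanged(self):
        ca = self._aif()
        r = synthetic.residue_function(ResidueModel(), ca.times)
        ct_conc = (400 / 6000.0) * 0.9 * np.convolve(ca.conc, r)[: len(ca.times)]
        base = deconvolve(ConcentrationCurve(ca.times, ct_conc), ca,
                          RegularizationSpec(1e-12)).rbf
        shift = 3
        ca_s = ConcentrationCurve(ca.times, np.roll(ca.conc, shift))
        ct_s = ConcentrationCurve(ca.times, np.roll(ct_conc, shift))
        shifted = deconvolve(ct_s, ca_s, RegularizationSpec(1e-12)).rbf
        assert abs(shifted - base) / base < 0.01

    def test_length_mismatch_rejected(self):
        ca = self._aif(n=50)
        ct = ConcentrationCurve(np.arange(40) * 0.9, np.ones(40))
        with pytest.raises(ValueError, match="mismatch"):
            deconvolve(ct, ca)

    def test_silent_aif_rejected(self):
        times = np.arange(50) * 0.9
        ca = ConcentrationCurve(times, np.zeros(50))
        with pytest.raises(ValueError, match="peak"):
            deconvolve(ConcentrationCurve(times, np.ones(50)), ca)


@pytest.fixture(scope="module")
def prepared(small_truth, noise_free_dce):
    norm = normalize_baseline(noise_free_dce)
    trunc = truncate_first_pass(norm, 50)
    single = DCESeries(trunc.volumes[:, :, 0, :], dt=0.9, n_baseline=15,
                       is_concentration=True)
    aif = extract_aif(single, small_truth.aorta)
    return single, aif


class TestRbfMap:
    def test_zero_tissue_gives_zero_map(self, prepared, small_truth):
        single, aif = prepared
        background = ~(small_truth.tissue | small_truth.aorta)
        pmap = rbf_map(single, aif, background, RegularizationSpec(1e-12))
        np.testing.assert_allclose(pmap.values[background], 0.0, atol=1e-6)

    def test_noise_free_cortex_within_5_percent(self, prepared, small_truth):
        single, aif = prepared
        pmap = rbf_map(single, aif, small_truth.tissue, RegularizationSpec(1e-12))
        got = pmap.values[small_truth.cortex_left].mean()
        assert got == pytest.approx(316.0, rel=0.05)

    def test_doubling_aif_halves_flow(self, prepared, small_truth):
        single, aif = prepared
        doubled = AIF(ConcentrationCurve(aif.curve.times, 2 * aif.curve.conc))
        base = rbf_map(single, aif, small_truth.cortex_left, RegularizationSpec(1e-12))
        halved = rbf_map(single, doubled, small_truth.cortex_left,
                         RegularizationSpec(1e-12))
        sel = small_truth.cortex_left
        np.testing.assert_allclose(halved.values[sel], base.values[sel] / 2,
                                   rtol=1e-8)

    def test_global_signal_scaling_cancels(self, prepared, small_truth):
        single, aif = prepared
        k = 3.7
        scaled_series = DCESeries(k * single.volumes, dt=0.9, n_baseline=15,
                                  is_concentration=True)
        scaled_aif = AIF(ConcentrationCurve(aif.curve.times, k * aif.curve.conc))
        base = rbf_map(single, aif, small_truth.cortex_right,
                       RegularizationSpec(1e-12))
        scaled = rbf_map(scaled_series, scaled_aif, small_truth.cortex_right,
                         RegularizationSpec(1e-12))
        sel = small_truth.cortex_right
        np.testing.assert_allclose(scaled.values[sel], base.values[sel], rtol=1e-8)

    def test_unnormalised_series_rejected(self, small_truth, noise_free_dce):
        aif_dummy = AIF(ConcentrationCurve(noise_free_dce.times,
                                           np.ones(noise_free_dce.n_volumes)))
        with pytest.raises(ValueError, match="normalis"):
            rbf_map(
                DCESeries(noise_free_dce.volumes[:, :, 0, :], 0.9, 15),
                aif_dummy, small_truth.tissue,
            )


class TestRegularisation:
    def test_stronger_truncation_never_raises_variance(self, small_truth):
        """Flow-estimate spread across noise replicates is non-increasing
        along an increasing threshold grid."""
        times = np.arange(50) * 0.9
        thresholds = (0.001, 0.02, 0.15)
        ests = {t: [] for t in thresholds}
        for rep in range(20):
            series = synthetic.simulate_dce(
                small_truth, AIFModel(), ResidueModel(),
                noise_sigma=0.003, seed=900 + rep,
            )
            norm = truncate_first_pass(normalize_baseline(series), 50)
            single = DCESeries(norm.volumes[:, :, 0, :], 0.9, 15,
                               is_concentration=True)
            aif = extract_aif(single, small_truth.aorta)
            ct = roi_concentration_curve(single, small_truth.cortex_right)
            for t in thresholds:
                ests[t].append(deconvolve(ct, aif.curve,
                                          RegularizationSpec(t)).rbf)
        sds = [np.std(ests[t], ddof=1) for t in thresholds]
        assert sds[0] >= sds[1] >= sds[2]


class TestMultisliceRoiMean:
    def _map(self, value, shape=(4, 4)):
        return PerfusionMap(np.full(shape, float(value)),
                            np.ones(shape, bool), "DCE")

    def test_identical_slices_match_single_slice(self):
        roi = np.ones((4, 4), bool)
        maps = [self._map(250.0)] * 3
        assert multislice_roi_mean(maps, roi) == 250.0

    def test_mean_of_slice_means(self):
        roi = np.ones((4, 4), bool)
        maps = [self._map(v) for v in (300, 400, 500)]
        assert multislice_roi_mean(maps, roi) == 400.0

    def test_empty_slice_skipped_with_warning(self):
        roi = np.ones((4, 4), bool)
        empty = PerfusionMap(np.zeros((4, 4)), np.zeros((4, 4), bool), "DCE")
        with pytest.warns(UserWarning, match="skipped"):
            got = multislice_roi_mean([self._map(300), empty], roi)
        assert got == 300.0

    def test_all_slices_empty_rejected(self):
        roi = np.zeros((4, 4), bool)
        with pytest.raises(ValueError, match="every slice"):
            multislice_roi_mean([self._map(1.0)], roi)

    def test_three_slice_phantom_replicates_truth(self, small_truth, noise_free_dce):
        from renperf.pipeline import quantify_dce_series

        maps, _ = quantify_dce_series(
            noise_free_dce, small_truth.aorta, small_truth.tissue, 50,
            RegularizationSpec(1e-12),
        )
        assert len(maps) == 3
        got = multislice_roi_mean(maps, small_truth.cortex_right)
        assert got == pytest.approx(416.0, rel=1e-9)
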