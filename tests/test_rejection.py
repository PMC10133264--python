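import numpy as np
import pytest
from scipy import stats

import seegflow as sf
from seegflow.rejection import (RejectionMask, _fuzzy_cmeans,
                                combine_rejections, detrend_trial,
                                feature_vector_outliers, flatness_detector,
                                glitch_detector, interictal_trial_detector,
                                mahalanobis_threshold, rejection_report,
                                trial_amplitude_outliers,
                                wavelet_blob_outliers)
from seegflow.simulate import ArtifactSpec, SimConfig, inject_artifacts, \
    simulate_dataset

from conftest import make_tensor


class TestDetrend:
    def test_constant_trace_gives_zeros(self):
        out = detrend_trial(np.full(100, 5.0))
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_exact_line_gives_zeros(self):
        t = np.arange(200.0)
        np.testing.assert_allclose(detrend_trial(3.0 + 0.7 * t), 0.0,
                                   atol=1e-8)

    def test_matches_normal_equations_residual(self, rng):
        t = np.arange(500.0)
        y = np.sin(0.07 * t) + 2.0 + 0.01 * t
        X = np.column_stack([np.ones_like(t), t])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(detrend_trial(y), y - X @ beta, atol=1e-9)


class TestFeatureVector:
    def test_reference_distance_at_97_5(self):
        assert round(mahalanobis_threshold(97.5), 4) == 2.7162

    def test_gross_amplitude_outlier_flagged(self, white_tensor):
        t = white_tensor.copy()
        t.data[1, 5, :] *= 100.0
        flags = feature_vector_outliers(t, 97.5)
        assert flags[1, 5]

    def test_gaussian_false_positive_rate(self):
        """On well-behaved noise the flagged fraction approaches the nominal
        2.5 % at percentile 97.5 (large trial count)."""
        rates = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            t = make_tensor(rng.standard_normal((1, 2000, 400)),
                            onset_index=200)
            flags = feature_vector_outliers(t, 97.5)
            rates.append(flags.mean())
        assert abs(np.mean(rates) - 0.025) < 0.01

    def test_too_few_trials_skips_with_warning(self, rng):
        t = make_tensor(rng.standard_normal((1, 5, 300)), onset_index=150)
        with pytest.warns(UserWarning, match="valid trials"):
            flags = feature_vector_outliers(t, 97.5)
        assert not flags.any()


class TestWaveletBlobs:
    def test_injected_gamma_burst_flagged(self, rng):
        t = make_tensor(rng.standard_normal((4, 20, 1500)), onset_index=750)
        out, gt = inject_artifacts(
            t, [ArtifactSpec("gamma_blob", trial=3, lead=1, start_ms=-200.0,
                             amplitude=10.0, freq_hz=80.0,
                             duration_ms=200.0)], 0)
        flags, blobs = wavelet_blob_outliers(out, return_blobs=True)
        assert flags[1, 3]
        hit = [b for b in blobs if b.lead == 1 and b.trial == 3][0]
        assert hit.centroid_freq_hz > 10.0
        assert hit.area >= 1

    def test_identical_trials_tie_break_flags_none(self, rng):
        trace = rng.standard_normal(1200)
        t = make_tensor(np.tile(trace, (2, 10, 1)), onset_index=600)
        flags = wavelet_blob_outliers(t)
        # all pooled intensities tie; strict > at the percentile flags none
        assert not flags.any()


class TestInterictal:
    def test_emd_between_identical_histograms_is_zero(self):
        centers = np.linspace(0, 1, 20)
        h = np.random.default_rng(0).random(20)
        assert stats.wasserstein_distance(centers, centers, h, h) == 0.0

    def test_coherent_trials_recovered_exactly(self, rng):
        t = make_tensor(rng.standard_normal((5, 30, 1500)), onset_index=750)
        bad = (4, 11, 23)
        specs = [ArtifactSpec("interictal_coherent", trial=tr, amplitude=8.0,
                              start_ms=-300.0, duration_ms=300.0)
                 for tr in bad]
        out, _ = inject_artifacts(t, specs, 0)
        found = interictal_trial_detector(out, rng=np.random.default_rng(0))
        assert found == set(bad)

    def test_exchangeable_trials_trigger_guard(self, rng):
        t = make_tensor(rng.standard_normal((4, 24, 1200)), onset_index=600)
        with pytest.warns(UserWarning, match="no coherent-event cluster"):
            found = interictal_trial_detector(t, rng=np.random.default_rng(1))
        assert found == set()

    def test_fuzzy_cmeans_separates_two_clouds(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (20, 3)),
                       rng.normal(5, 0.1, (6, 3))])
        u = _fuzzy_cmeans(X, rng)
        hard = u.argmax(axis=1)
        assert len(set(hard[:20])) == 1 and len(set(hard[20:])) == 1
        assert hard[0] != hard[-1]


class TestTrialAmplitude:
    def test_identical_trials_yield_empty_set(self):
        t = make_tensor(np.ones((2, 6, 100)), onset_index=50)
        assert trial_amplitude_outliers(t) == set()

    def test_single_large_trial_flagged(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((2, 5, 200))
        data[:, 4, :] *= 10.0
        t = make_tensor(data, onset_index=100)
        # independent check: the MAD rule on the statistic vector itself
        stat = np.abs(data).max(axis=(0, 2))
        med = np.median(stat)
        mad = 1.4826 * np.median(np.abs(stat - med))
        assert abs(stat[4] - med) > 3 * mad
        assert 4 in trial_amplitude_outliers(t)


class TestGlitch:
    def test_coherent_step_flagged(self, rng):
        data = rng.standard_normal((6, 12, 800))
        data[:, 5, 400:] += 50.0
        t = make_tensor(data, onset_index=400)
        assert glitch_detector(t, 3.0) == {5}

    def test_smooth_signals_pass(self, rng):
        from scipy.signal import sosfiltfilt, butter
        sos = butter(4, 40.0, fs=1000.0, output="sos")
        data = sosfiltfilt(sos, rng.standard_normal((4, 10, 800)), axis=-1)
        t = make_tensor(data, onset_index=400)
        assert glitch_detector(t, 5.0) == set()

    def test_single_lead_step_diluted_by_mean(self, rng):
        data = rng.standard_normal((100, 10, 600))
        data[0, 4, 300:] += 8.0  # one lead of 100: mean |diff| barely moves
        t = make_tensor(data, onset_index=300)
        assert 4 not in glitch_detector(t, 5.0)


class TestFlatness:
    def test_long_constant_segment_flagged(self, rng):
        data = rng.standard_normal((2, 4, 1000))
        data[0, 2, 100:400] = data[0, 2, 100]  # 3 x winlen
        t = make_tensor(data, onset_index=500)
        flags = flatness_detector(t, winlen=100, winstep=50, replen=3)
        assert flags[0, 2] and flags.sum() == 1

    def test_continuous_noise_not_flagged(self, rng):
        t = make_tensor(rng.standard_normal((3, 5, 1000)), onset_index=500)
        assert not flatness_detector(t, 100, 50, 3).any()

    def test_segment_shorter_than_window_not_flagged(self, rng):
        data = rng.standard_normal((1, 3, 1000))
        data[0, 1, 100:199] = data[0, 1, 100]  # winlen - 1
        t = make_tensor(data, onset_index=500)
        assert not flatness_detector(t, winlen=100, winstep=50, replen=0).any()


class TestCombine:
    def _masks(self, n_leads=8, n_trials=10):
        shape = (n_leads, n_trials)
        return {
            "feature_vector": np.zeros(shape, bool),
            "wavelet": np.zeros(shape, bool),
            "flatness": np.zeros(shape, bool),
            "interictal": set(),
            "amplitude": set(),
            "glitch": set(),
        }

    def test_trial_removed_when_above_lead_threshold(self):
        per = self._masks()
        per["interictal"] = {3}
        per["feature_vector"][:6, 3] = True  # 6 > 5
        m = combine_rejections(per, lead_threshold=5)
        assert m.removed_trials == {3}
        assert m.combined[:, 3].all()

    def test_trial_kept_below_lead_threshold(self):
        per = self._masks()
        per["interictal"] = {3}
        per["feature_vector"][:3, 3] = True  # 3 <= 5
        m = combine_rejections(per, lead_threshold=5)
        assert m.removed_trials == set()
        assert m.combined[:3, 3].all() and not m.combined[3:, 3].any()

    def test_glitch_trials_removed_unconditionally(self):
        per = self._masks()
        per["glitch"] = {7}
        m = combine_rejections(per, lead_threshold=5)
        assert m.removed_trials == {7}
        assert m.combined[:, 7].all()

    def test_combined_is_superset_of_each_mask(self):
        per = self._masks()
        rng = np.random.default_rng(0)
        for key in ("feature_vector", "wavelet", "flatness"):
            per[key] = rng.random((8, 10)) < 0.2
        m = combine_rejections(per, lead_threshold=5)
        for key in ("feature_vector", "wavelet", "flatness"):
            assert (m.combined | ~per[key]).all()

    def test_shape_mismatch_rejected(self):
        per = self._masks()
        per["wavelet"] = np.zeros((3, 10), bool)
        with pytest.raises(ValueError, match="shape"):
            combine_rejections(per, 5)


class TestReport:
    def test_fraction_and_medians(self):
        combined = np.zeros((100, 128), bool)
        combined.ravel()[:1024] = True
        m = RejectionMask({}, set(), combined)
        t = make_tensor(np.zeros((100, 128, 10)), onset_index=5)
        rep = rejection_report(m, t)
        assert rep["fraction_rejected"][0] == pytest.approx(0.08)

    def test_no_masking_identity(self):
        combined = np.zeros((4, 20), bool)
        m = RejectionMask({}, set(), combined)
        t = make_tensor(np.zeros((4, 20, 10)), onset_index=5)
        rep = rejection_report(m, t)
        assert rep["fraction_rejected"][0] == 0.0
        assert rep["median_trials_per_lead"][0] == 20
        assert rep["min_trials_per_lead"][0] == 20

    def test_union_not_double_counted(self):
        per = {
            "feature_vector": np.zeros((4, 10), bool),
            "wavelet": np.zeros((4, 10), bool),
            "flatness": np.zeros((4, 10), bool),
        }
        per["feature_vector"][0, 0] = True
        per["wavelet"][0, 0] = True  # overlap
        m = combine_rejections(per, 5)
        t = make_tensor(np.zeros((4, 10, 10)), onset_index=5)
        rep = rejection_report(m, t)
        assert rep["rejected_lead_trials"][0] == 1
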