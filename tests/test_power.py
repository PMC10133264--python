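import numpy as np
import pytest

import seegflow as sf
from seegflow.config import PipelineConfig
from seegflow.power import (band_center_frequencies, classify_lead,
                            gamma_power_timecourse, gc_power_correlation,
                            latency_duration, zscore_vs_baseline)

from conftest import make_tensor


def _sine_tensor(freq, amp=1.0, n=2000, fs=1000.0):
    t = np.arange(n) / fs
    return make_tensor((amp * np.sin(2 * np.pi * freq * t))[None, None, :],
                       fs=fs, onset_index=1000)


class TestGammaPower:
    def test_band_centers(self):
        np.testing.assert_array_equal(
            band_center_frequencies((50.0, 150.0)),
            [55.0, 65.0, 75.0, 85.0, 95.0, 105.0, 115.0, 125.0, 135.0, 145.0],
        )

    def test_zero_signal_zero_power(self):
        p = gamma_power_timecourse(make_tensor(np.zeros((2, 3, 1000)),
                                               onset_index=500))
        np.testing.assert_allclose(p.values, 0.0, atol=1e-20)

    def test_power_scales_with_amplitude_squared(self):
        p1 = gamma_power_timecourse(_sine_tensor(100.0, 1.0))
        p2 = gamma_power_timecourse(_sine_tensor(100.0, 2.0))
        ratio = np.nanmean(p2.values) / np.nanmean(p1.values)
        assert ratio == pytest.approx(4.0, rel=0.01)

    @pytest.mark.parametrize("family,leak", [("morse", 1e-3),
                                             ("morlet", 5e-3)])
    def test_out_of_band_tone_attenuated(self, family, leak):
        cfg = PipelineConfig(power_wavelet=family)
        p_in = gamma_power_timecourse(_sine_tensor(100.0), cfg)
        p_out = gamma_power_timecourse(_sine_tensor(30.0), cfg)
        assert np.nanmean(p_out.values) < leak * np.nanmean(p_in.values)

    def test_masked_combination_stays_nan(self, rng):
        t = make_tensor(rng.standard_normal((2, 4, 1000)), onset_index=500)
        t.mask[0, 1, :] = True
        p = gamma_power_timecourse(t)
        assert np.isnan(p.values[0, 1]).all()
        assert np.isfinite(p.values[1]).all()


class TestZScore:
    def test_stationary_noise_baseline_standardized(self, rng):
        t = make_tensor(rng.standard_normal((3, 30, 2000)), onset_index=1000)
        z = zscore_vs_baseline(gamma_power_timecourse(t))
        base = z.bin_times_ms < 0
        np.testing.assert_allclose(z.values[:, base].mean(axis=1), 0.0,
                                   atol=1e-9)
        np.testing.assert_allclose(z.values[:, base].std(axis=1), 1.0,
                                   rtol=1e-9)

    def test_constant_power_raises(self):
        t = make_tensor(np.ones((1, 5, 1000)), onset_index=500)
        p = gamma_power_timecourse(t)
        with pytest.raises(ValueError, match="baseline SD"):
            zscore_vs_baseline(p)


class TestClassifyLead:
    times = np.arange(-1000.0, 1000.0, 25.0) + 12.5

    def _z(self, sep_peak, vep_peak=1.0):
        z = np.zeros_like(self.times)
        z[(self.times >= 75) & (self.times < 275)] = sep_peak
        z[(self.times >= 700) & (self.times < 900)] = vep_peak
        return z

    def test_responsive_and_selective(self):
        cls = classify_lead(self._z(4.0), self._z(1.0), self.times,
                            video_epoch_ms=(700.0, 900.0))
        assert cls.responsive and cls.selective

    def test_below_threshold_not_responsive(self):
        cls = classify_lead(self._z(2.0), self._z(1.0), self.times,
                            video_epoch_ms=(700.0, 900.0))
        assert not cls.responsive

    def test_task_unspecific_not_selective(self):
        cls = classify_lead(self._z(4.0), self._z(4.0), self.times,
                            video_epoch_ms=(700.0, 900.0))
        assert cls.responsive and not cls.selective

    def test_video_epoch_response_breaks_selectivity(self):
        cls = classify_lead(self._z(4.0, vep_peak=5.0), self._z(1.0),
                            self.times, video_epoch_ms=(700.0, 900.0))
        assert cls.responsive and not cls.selective

    def test_missing_action_task_warns(self):
        with pytest.warns(UserWarning, match="action task missing"):
            cls = classify_lead(self._z(4.0), None, self.times,
                                video_epoch_ms=(700.0, 900.0))
        assert cls.responsive and not cls.selective


class TestLatencyDuration:
    def test_exact_piecewise_linear_geometry(self):
        t = np.arange(0.0, 500.0, 25.0)
        z = np.interp(t, [0, 100, 200, 300, 400], [0, 0, 4, 0, 0])
        lat, dur = latency_duration(z, t, threshold=2.0)
        assert lat == pytest.approx(150.0)
        assert dur == pytest.approx(100.0)

    def test_no_crossing_undefined(self):
        t = np.arange(0.0, 500.0, 25.0)
        lat, dur = latency_duration(np.full_like(t, 1.9), t, 2.0)
        assert np.isnan(lat) and np.isnan(dur)

    @pytest.mark.parametrize("shift", [-50.0, 0.0, 75.0])
    def test_shift_equivariance(self, shift):
        t = np.arange(0.0, 500.0, 25.0)
        z = np.exp(-((t - 200.0) ** 2) / (2 * 50.0 ** 2)) * 5
        lat0, _ = latency_duration(z, t, 2.0)
        lat1, _ = latency_duration(z, t + shift, 2.0)
        if lat0 + shift >= 0:
            assert lat1 == pytest.approx(lat0 + shift)


class TestGCPowerCorrelation:
    def test_exact_linear_dependence(self):
        src = np.array([1.0, 2.0, 3.0, 4.0])
        out = gc_power_correlation(2 * src + 1, src, np.ones(4) * 2)
        assert out["source"] == pytest.approx(1.0)
        assert np.isnan(out["target"])  # zero variance guard

    def test_constant_strengths_undefined(self):
        out = gc_power_correlation(np.ones(5), np.arange(5.0), np.arange(5.0))
        assert np.isnan(out["source"])

    def test_independent_samples_weakly_correlated(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            out = gc_power_correlation(rng.standard_normal(100),
                                       rng.standard_normal(100),
                                       rng.standard_normal(100))
            if abs(out["source"]) < 0.3:
                hits += 1
        assert hits >= 19

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            gc_power_correlation(np.ones(2), np.ones(2), np.ones(2))
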