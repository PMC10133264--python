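import numpy as np
import pytest
from scipy.linalg import solve_discrete_lyapunov, toeplitz

import seegflow as sf
from seegflow.config import PipelineConfig
from seegflow.granger import (classify_connection, conditioned_gc,
                              connection_strength, fit_var_window,
                              gc_from_fit, pairwise_ugc, peak_response_z,
                              region_average_gc, select_pair_trials,
                              surrogate_normalize, via_lead_classification,
                              GCTrace)
from seegflow.simulate import CouplingSpec, SimConfig, simulate_dataset

from conftest import make_tensor


def analytic_var1_gc(a, b, c, order):
    """Closed-form time-domain GC x->y for the bivariate VAR(1)
    x[t] = a x[t-1] + e,  y[t] = c x[t-1] + b y[t-1] + f  (unit noises),
    against a reduced autoregression of y of the given order, from the
    analytically computed autocovariances (Yule-Walker)."""
    A = np.array([[a, 0.0], [c, b]])
    G0 = solve_discrete_lyapunov(A, np.eye(2))
    gam = [(np.linalg.matrix_power(A, k) @ G0)[1, 1]
           for k in range(order + 1)]
    R = toeplitz(gam[:order])
    r = np.array(gam[1:order + 1])
    var_red = gam[0] - r @ np.linalg.solve(R, r)
    return np.log(var_red)  # full-model innovation variance is exactly 1


def simulate_var1(a, b, c, n, seed):
    rng = np.random.default_rng(seed)
    e = rng.standard_normal((2, n))
    x = np.zeros((2, n))
    A = np.array([[a, 0.0], [c, b]])
    for t in range(1, n):
        x[:, t] = A @ x[:, t - 1] + e[:, t]
    return x


class TestVarFit:
    def test_known_var1_coefficients_recovered(self):
        x = simulate_var1(0.5, 0.5, 0.4, 100_000, 0)
        fit = fit_var_window(x[:, None, :], order=1)
        coefs = fit["coefs"]
        assert coefs[0, 0] == pytest.approx(0.5, abs=0.05)
        assert coefs[1, 0] == pytest.approx(0.4, abs=0.05)
        assert coefs[1, 1] == pytest.approx(0.5, abs=0.05)

    def test_independent_leads_have_null_cross_coefficients(self, rng):
        data = rng.standard_normal((2, 200, 100))
        fit = fit_var_window(data, order=4)
        coefs = fit["coefs"]
        assert np.abs(coefs[0, 4:]).max() < 0.05
        assert np.abs(coefs[1, :4]).max() < 0.05

    def test_order_zero_rejected(self, rng):
        with pytest.raises(ValueError, match="order"):
            fit_var_window(rng.standard_normal((2, 5, 50)), order=0)

    def test_gc_nonnegative(self, rng):
        for _ in range(20):
            fit = fit_var_window(rng.standard_normal((2, 10, 100)), order=4)
            assert gc_from_fit(fit, 0, 1) >= -1e-10
            assert gc_from_fit(fit, 1, 0) >= -1e-10


class TestOracleEquivalence:
    def test_time_domain_gc_matches_closed_form(self):
        """Engine GC on a long stationary VAR(1) realization agrees with the
        analytic reduced/full innovation-variance ratio within 5 %."""
        F_true = analytic_var1_gc(0.5, 0.5, 0.4, order=4)
        x = simulate_var1(0.5, 0.5, 0.4, 300_000, 42)
        fit = fit_var_window(x[:, None, :], order=4)
        F_hat = gc_from_fit(fit, 0, 1)
        assert F_hat == pytest.approx(F_true, rel=0.05)
        # reverse direction is an order of magnitude weaker
        assert gc_from_fit(fit, 1, 0) < 0.1 * F_hat


class TestPairwise:
    def test_select_pair_trials_set_algebra(self, white_tensor):
        t = white_tensor.copy()
        t.mask[0, [1, 2], :] = True
        t.mask[1, [2, 3], :] = True
        trials = select_pair_trials(t, (0, 1), min_common=3)
        assert set(trials) == set(range(24)) - {1, 2, 3}

    def test_disjoint_valid_sets_skipped_with_warning(self, white_tensor):
        t = white_tensor.copy()
        t.mask[0, :12, :] = True
        t.mask[1, 12:, :] = True
        with pytest.warns(UserWarning, match="common trials"):
            assert select_pair_trials(t, (0, 1)) is None

    def test_directionality_and_strength(self):
        cfg = PipelineConfig()
        sim = SimConfig(n_leads=2, n_trials_per_task=20,
                        couplings=[CouplingSpec(0, 1, 2.0, 0.4)])
        t, _ = simulate_dataset(sim, 0)
        g = np.flatnonzero(t.trial_labels["task"] == "gender")
        trials = select_pair_trials(t, (0, 1), trials=g)
        fw, bw = pairwise_ugc(t, (0, 1), 1, cfg, trials)
        for tr in (fw, bw):
            sf.baseline_zscore_gc(tr, t, cfg)
        C_fw = connection_strength(fw.baseline_z, fw.times_ms,
                                   window_len_ms=fw.window_len_ms)
        C_bw = connection_strength(bw.baseline_z, bw.times_ms,
                                   window_len_ms=bw.window_len_ms)
        assert C_fw > 5.0
        assert C_bw < C_fw

    def test_surrogate_determinism(self, white_tensor):
        cfg = PipelineConfig(n_surrogate=4)
        trials = np.arange(24)
        out = []
        for _ in range(2):
            fw, bw = pairwise_ugc(white_tensor, (0, 1), 1, cfg, trials)
            surrogate_normalize(white_tensor, (fw, bw), 1, cfg,
                                np.random.default_rng(9), trials)
            out.append(fw.surrogate_z.copy())
        np.testing.assert_array_equal(out[0], out[1])

    def test_bootstrap_mean_tracks_point_estimate(self, white_tensor):
        from seegflow.granger import bootstrap_gc
        cfg = PipelineConfig(n_bootstrap=5, gc_offset_samples=200)
        trials = np.arange(24)
        fw, bw = pairwise_ugc(white_tensor, (0, 1), 1, cfg, trials)
        means, sds = bootstrap_gc(white_tensor, (0, 1), 1, cfg,
                                  np.random.default_rng(3), trials)
        assert means.shape == (2, len(fw.f)) and sds.shape == means.shape
        assert (sds >= 0).all()
        # bootstrap mean stays on the scale of the point estimate
        assert abs(means[0].mean() - fw.f.mean()) < 5 * fw.f.mean()

    def test_frequency_domain_grid(self, white_tensor):
        cfg = PipelineConfig(gc_offset_samples=500)
        fw, _ = pairwise_ugc(white_tensor, (0, 1), 4, cfg, np.arange(24),
                             compute_freq=True)
        assert fw.freq_hz.shape == (101,)
        assert fw.freq_hz[0] == 0.0
        assert fw.freq_hz[-1] == pytest.approx(125.0)  # NS4 Nyquist


class TestBaselineZ:
    def _trace(self, f):
        starts = np.arange(0, 1901, 10)
        times = (starts + 50 - 1000.0)
        return GCTrace(0, 1, 1, starts, times, np.asarray(f, float))

    def test_definition(self):
        starts = np.arange(0, 1901, 10)
        f = np.zeros(len(starts))
        base = (starts >= 100) & (starts + 100 <= 1000)
        rng = np.random.default_rng(0)
        f[base] = rng.normal(1.0, 0.1, base.sum())
        mu, sd = f[base].mean(), f[base].std()
        f[-10] = mu + 5 * sd
        tr = self._trace(f)
        tensor = make_tensor(np.zeros((2, 2, 2000)), onset_index=1000)
        sf.baseline_zscore_gc(tr, tensor)
        assert tr.baseline_z[-10] == pytest.approx(5.0)

    def test_constant_trace_undefined(self):
        tr = self._trace(np.ones(191))
        tensor = make_tensor(np.zeros((2, 2, 2000)), onset_index=1000)
        sf.baseline_zscore_gc(tr, tensor)
        assert np.isnan(tr.baseline_z).all()


class TestStrengthRule:
    times = np.arange(100.0, 401.0, 10.0)

    def _C(self, vals):
        return connection_strength(np.asarray(vals, float),
                                   self.times[:len(vals)],
                                   response_window_s=(0.05, 0.45))

    def test_both_positive_takes_max(self):
        assert self._C([7.0, 1.0, 2.0]) == 7.0

    def test_both_negative_takes_min(self):
        assert self._C([-1.0, -6.0, -2.0]) == -6.0

    def test_mixed_close_takes_mean(self):
        assert self._C([2.0, -0.5, 1.0]) == pytest.approx(0.75)

    def test_mixed_far_takes_larger_magnitude(self):
        assert self._C([6.0, -2.0, 0.0]) == 6.0

    def test_uncovered_window_rejected(self):
        with pytest.raises(ValueError, match="response window"):
            connection_strength(np.ones(3), np.array([-500.0, -400, -300]))


class TestTyping:
    @pytest.mark.parametrize("c1,c4,expected", [
        (6.0, 2.0, "D"),
        (6.0, 7.0, "M"),
        (2.0, 6.0, "A"),
        (1.0, -6.0, "N"),
        (-6.0, 6.0, "opposite"),
        (6.0, -6.0, "opposite"),
        (2.0, 2.0, "weak"),
        (5.0, 5.0, "weak"),   # ties fall to the weaker category
    ])
    def test_rule_table(self, c1, c4, expected):
        assert classify_connection(c1, c4) == expected


class TestConditioning:
    def test_cond_lead_in_pair_rejected(self, white_tensor):
        with pytest.raises(ValueError, match="conditioning lead"):
            conditioned_gc(white_tensor, (0, 1), 0)

    def test_common_driver_explained_away(self):
        cfg = PipelineConfig()
        sim = SimConfig(n_leads=4, n_trials_per_task=20, couplings=[
            CouplingSpec(2, 0, 2.0, 0.9), CouplingSpec(2, 1, 4.0, 0.9)])
        t, _ = simulate_dataset(sim, 13)
        g = np.flatnonzero(t.trial_labels["task"] == "gender")
        trials = select_pair_trials(t, (0, 1), trials=g)
        fw, _ = pairwise_ugc(t, (0, 1), 1, cfg, trials)
        sf.baseline_zscore_gc(fw, t, cfg)
        assert peak_response_z(fw, cfg) > 5.0
        rng = np.random.default_rng(1)
        cond = conditioned_gc(t, (0, 1), 2, 1, cfg, rng, trials=trials)
        assert peak_response_z(cond, cfg) < 3.0
        indep = conditioned_gc(t, (0, 1), 3, 1, cfg, rng, trials=trials)
        assert peak_response_z(indep, cfg) > 5.0


class TestViaAndAveraging:
    @pytest.mark.parametrize("c_in,c_out,expected", [
        (6.0, 6.0, True), (6.0, 4.0, False), (4.0, 4.0, False),
    ])
    def test_via_rule(self, c_in, c_out, expected):
        assert via_lead_classification(c_in, c_out) is expected

    def test_region_average(self):
        starts = np.arange(0, 100, 10)
        times = starts + 50.0
        t1 = GCTrace(0, 1, 1, starts, times, np.full(10, 2.0))
        t2 = GCTrace(0, 2, 1, starts, times, np.full(10, 4.0))
        avg = region_average_gc([t1, t2])
        np.testing.assert_allclose(avg.f, 3.0)
        single = region_average_gc([t1])
        np.testing.assert_allclose(single.f, t1.f)
        with pytest.raises(ValueError):
            region_average_gc([])


class TestStrengthProperties:
    """Invariants of the C rule over arbitrary finite traces."""

    from hypothesis import given, settings, strategies as st

    @given(st.lists(st.floats(-20, 20), min_size=2, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_strength_bounded_by_trace_extremes(self, vals):
        import numpy as np
        times = np.linspace(150.0, 350.0, len(vals))
        C = connection_strength(np.array(vals), times,
                                response_window_s=(0.1, 0.4))
        assert min(vals) - 1e-9 <= C <= max(vals) + 1e-9

    @given(st.lists(st.floats(0.1, 20), min_size=2, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_all_positive_gives_max(self, vals):
        import numpy as np
        times = np.linspace(150.0, 350.0, len(vals))
        C = connection_strength(np.array(vals), times,
                                response_window_s=(0.1, 0.4))
        assert C == max(vals)
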