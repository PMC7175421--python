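"""Tests of truncated-MLE dwell-time fitting, run/velocity fits and statistics."""

import numpy as np
import pytest

from myofil import kinetics
from myofil.simulate import sample_dwell_times
from myofil.stack import ImageStack


class TestExpMixtureFit:
    def test_k1_untruncated_equals_sample_mean(self):
        t = sample_dwell_times([(1.0, 2.0)], 500, seed=0)
        fit = kinetics.fit_exp_mixture(t, 1)
        assert fit.taus[0] == pytest.approx(t.mean(), abs=1e-12)

    def test_k1_truncated_recovery_unbiased_naive_biased(self):
        # tau = 0.34 s with t_min = 0.3 s: the truncated likelihood is
        # unbiased while the naive mean is shifted by ~t_min
        t = sample_dwell_times([(1.0, 0.34)], 60_000, seed=1)
        t = t[t >= 0.3][:10_000]
        fit = kinetics.fit_exp_mixture(t, 1, t_min_s=0.3)
        assert fit.taus[0] == pytest.approx(0.34, rel=0.05)
        naive = kinetics.fit_exp_mixture(t, 1)
        assert naive.taus[0] > 1.5 * 0.34

    def test_k2_recovery_of_double_exponential(self):
        # kymograph-analysis parameters: (0.68, 1.23 s) + (0.32, 12.6 s)
        t = sample_dwell_times([(0.68, 1.23), (0.32, 12.6)], 6400, seed=1)
        fit = kinetics.fit_exp_mixture(t, 2, seed=0)
        assert 1.12 <= fit.taus[0] <= 1.36
        assert 11.3 <= fit.taus[1] <= 14.0
        assert 0.6 <= fit.fractions[0] <= 0.75

    def test_two_sided_truncation_consistent(self):
        t = sample_dwell_times([(1.0, 2.0)], 200_000, seed=2)
        t = t[(t >= 0.5) & (t <= 6.0)][:20_000]
        fit = kinetics.fit_exp_mixture(t, 1, t_min_s=0.5, t_max_s=6.0)
        assert fit.taus[0] == pytest.approx(2.0, rel=0.05)

    def test_taus_ascending_fractions_sum_to_one(self):
        t = sample_dwell_times([(0.5, 0.5), (0.5, 8.0)], 2000, seed=3)
        fit = kinetics.fit_exp_mixture(t, 2, seed=0)
        assert fit.taus[0] < fit.taus[1]
        assert fit.fractions.sum() == pytest.approx(1.0)

    def test_collapsed_components_fall_back(self):
        t = sample_dwell_times([(1.0, 2.0)], 500, seed=4)
        with pytest.warns(UserWarning, match="collapsed"):
            fit = kinetics.fit_exp_mixture(t, 2, seed=0)
        assert fit.collapsed
        assert fit.k == 1

    def test_data_outside_window_rejected(self):
        with pytest.raises(ValueError, match="within"):
            kinetics.fit_exp_mixture(np.linspace(0.1, 5, 50), 1, t_min_s=0.3)

    def test_deterministic_given_data_and_seed(self):
        t = sample_dwell_times([(0.6, 1.0), (0.4, 8.0)], 2000, seed=5)
        a = kinetics.fit_exp_mixture(t, 2, seed=7)
        b = kinetics.fit_exp_mixture(t, 2, seed=7)
        np.testing.assert_array_equal(a.taus, b.taus)


class TestBootstrap:
    def test_ci_width_matches_asymptotic_theory(self):
        # exponential MLE: sd(tau_hat) = tau/sqrt(n); CI width = 2*1.96*that
        tau, n = 2.0, 10_000
        t = sample_dwell_times([(1.0, tau)], n, seed=6)
        fit = kinetics.fit_exp_mixture(t, 1)
        ci = kinetics.bootstrap_ci(t, fit, B=500, seed=0)
        width = ci["tau0"][1] - ci["tau0"][0]
        assert width == pytest.approx(2 * 1.96 * tau / np.sqrt(n), rel=0.25)
        assert ci["tau0"][0] < fit.taus[0] < ci["tau0"][1]

    def test_ci_shrinks_with_sqrt_n(self):
        tau = 2.0
        widths = []
        for n in (2000, 8000):
            t = sample_dwell_times([(1.0, tau)], n, seed=7)
            fit = kinetics.fit_exp_mixture(t, 1)
            ci = kinetics.bootstrap_ci(t, fit, B=400, seed=1)
            widths.append(ci["tau0"][1] - ci["tau0"][0])
        assert widths[0] / widths[1] == pytest.approx(2.0, rel=0.25)

    def test_too_few_replicates_rejected(self):
        t = sample_dwell_times([(1.0, 1.0)], 100, seed=8)
        fit = kinetics.fit_exp_mixture(t, 1)
        with pytest.raises(ValueError):
            kinetics.bootstrap_ci(t, fit, B=50)


class TestModelSelection:
    def test_single_exponential_selects_k1(self):
        hits = 0
        for seed in range(5):
            t = sample_dwell_times([(1.0, 2.0)], 5000, seed=seed)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sel = kinetics.select_model(t, k_max=2)
            hits += sel["k_best"] == 1
        assert hits >= 4

    def test_triple_mixture_selects_k3_and_likelihood_nests(self):
        mix = [(0.55, 0.34), (0.35, 2.26), (0.10, 10.9)]
        t = sample_dwell_times(mix, 14_016, seed=1)
        t = t[t >= 0.3]
        sel = kinetics.select_model(t, k_max=3, t_min_s=0.3)
        assert sel["k_best"] == 3
        lls = [sel["logliks"][k] for k in (1, 2, 3)]
        assert lls[0] <= lls[1] <= lls[2]
        assert all(0 <= p <= 1 for p in sel["lrt_p"].values())


class TestRunLengths:
    def test_untruncated_mle_is_mean(self):
        rng = np.random.default_rng(9)
        r = rng.exponential(0.5, 200)
        fit = kinetics.fit_run_lengths(r)
        assert fit.lambda_um == pytest.approx(r.mean(), abs=1e-12)

    def test_recovery_at_small_sample(self):
        # lambda = 0.23 um at n = 432: estimate within its bootstrap CI
        rng = np.random.default_rng(10)
        r = rng.exponential(0.23, 432)
        fit = kinetics.fit_run_lengths(r)
        assert fit.ci95[0] <= 0.23 <= fit.ci95[1]

    def test_recovery_at_large_sample(self):
        # lambda = 1.03 um at n = 1133: within +-0.05 um
        rng = np.random.default_rng(11)
        r = rng.exponential(1.03, 1133)
        fit = kinetics.fit_run_lengths(r)
        assert fit.lambda_um == pytest.approx(1.03, abs=0.05)

    def test_left_truncation_shift(self):
        rng = np.random.default_rng(12)
        r = 0.03 + rng.exponential(0.5, 5000)
        fit = kinetics.fit_run_lengths(r, min_run_um=0.03)
        assert fit.lambda_um == pytest.approx(0.5, rel=0.05)

    def test_too_few_runs_rejected(self):
        with pytest.raises(ValueError):
            kinetics.fit_run_lengths([0.1] * 5)


class TestVelocities:
    def test_single_gaussian_mean(self):
        rng = np.random.default_rng(13)
        v = rng.normal(0.46, 0.20, 1133)
        fit = kinetics.fit_velocities(v, k=1)
        assert fit.means[0] == pytest.approx(0.46, abs=0.02)
        assert fit.sds[0] == pytest.approx(0.20, rel=0.1)

    def test_two_component_recovery(self):
        # slow 60% at 0.04, fast 40% at 0.20 um/s
        rng = np.random.default_rng(14)
        n = 432
        comp = rng.uniform(size=n) < 0.6
        v = np.where(comp, rng.normal(0.04, 0.03, n), rng.normal(0.20, 0.13, n))
        fit = kinetics.fit_velocities(v, k=2)
        assert fit.k == 2
        assert fit.means[0] == pytest.approx(0.04, abs=0.01)
        assert fit.means[1] == pytest.approx(0.20, rel=0.25)

    def test_equal_speeds_flagged_degenerate(self):
        with pytest.warns(UserWarning):
            fit = kinetics.fit_velocities(np.full(50, 0.3), k=1)
        assert fit.degenerate

    def test_em_deterministic(self):
        rng = np.random.default_rng(15)
        v = rng.normal(0.3, 0.1, 300)
        a = kinetics.fit_velocities(v, k=2)
        b = kinetics.fit_velocities(v, k=2)
        np.testing.assert_array_equal(a.means, b.means)


class TestCorrelationAndKS:
    def test_perfect_linear_pairs(self):
        d = np.linspace(0.5, 8, 60)
        out = kinetics.correlate_run_dwell(0.2 * d, d, split_s=3.0)
        assert out["short"][0] == pytest.approx(1.0)
        assert out["long"][0] == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(16)
        hits = 0
        for _ in range(10):
            runs = rng.exponential(1.0, 400)
            dwells = rng.exponential(2.0, 400)
            out = kinetics.correlate_run_dwell(runs, dwells, split_s=2.0)
            hits += abs(out["short"][0]) < 0.12
        assert hits >= 9

    def test_bivariate_normal_correlation_recovery(self):
        # rho = 0.57 at n = 300
        rng = np.random.default_rng(17)
        z = rng.multivariate_normal([1.0, 2.0],
                                    [[1, 0.57], [0.57, 1]], 300)
        out = kinetics.correlate_run_dwell(z[:, 0], z[:, 1], split_s=np.inf)
        assert out["short"] is not None
        assert 0.47 <= out["short"][0] <= 0.67

    def test_small_regime_omitted(self):
        out = kinetics.correlate_run_dwell([1, 2, 3, 4.], [1, 1.2, 1.4, 1.6],
                                           split_s=5.0)
        assert out["long"] is None

    def test_ks_identical_samples(self):
        a = np.linspace(0.1, 5, 100)
        D, p = kinetics.ks_compare(a, a)
        assert D == 0.0
        assert p == pytest.approx(1.0)

    def test_ks_null_pvalues_uniform(self):
        rng = np.random.default_rng(18)
        ps = []
        for _ in range(200):
            a = rng.exponential(2.0, 1000)
            b = rng.exponential(2.0, 1000)
            ps.append(kinetics.ks_compare(a, b)[1])
        assert np.mean(ps) == pytest.approx(0.5, abs=0.1)

    def test_ks_power_on_shifted_tail(self):
        # exp(2.2) vs exp(2.6), n = 2000 each, dwell times > 2 s
        rng = np.random.default_rng(19)
        hits = 0
        for _ in range(20):
            a = rng.exponential(2.2, 2000)
            b = rng.exponential(2.6, 2000)
            hits += kinetics.ks_compare(a, b, min_t_s=2.0)[1] < 0.05
        assert hits >= 10

    def test_ks_empty_after_filter_rejected(self):
        with pytest.raises(ValueError):
            kinetics.ks_compare([0.1, 0.2], [3.0, 4.0], min_t_s=2.0)


class TestKymograph:
    def _stack(self, frames):
        return ImageStack(frames=np.asarray(frames, float), dt_s=0.2,
                          pixel_size_nm=31.8)

    def test_static_spot_constant_stripe(self):
        frames = np.zeros((10, 32, 32))
        frames[:, 16, 10] = -0.05
        stk = self._stack(frames)
        kymo = kinetics.kymograph(stk, [(2, 16), (30, 16)], line_width_px=1)
        row = np.argmin(kymo[:, 0])
        assert np.allclose(kymo[row], kymo[row, 0])
        assert kymo[row, 0] < -0.04

    def test_moving_particle_stripe_slope(self):
        # particle at 2 px/frame along the line -> kymograph slope 2 px/frame
        n = 12
        frames = np.zeros((n, 16, 64))
        cols = 5 + 2 * np.arange(n)
        for f, c in enumerate(cols):
            frames[f, 8, c] = -1.0
        kymo = kinetics.kymograph(self._stack(frames), [(0, 8), (63, 8)],
                                  line_width_px=1)
        pos = np.argmin(kymo, axis=0)
        slope = np.polyfit(np.arange(n), pos, 1)[0]
        assert slope == pytest.approx(2.0, rel=0.1)

    def test_width_three_is_mean_of_offsets(self):
        rng = np.random.default_rng(20)
        frames = rng.normal(size=(3, 16, 32))
        stk = self._stack(frames)
        line = [(2.0, 8.0), (29.0, 8.0)]
        wide = kinetics.kymograph(stk, line, line_width_px=3)
        parts = [kinetics.kymograph(self._stack(frames),
                                    [(2.0, 8.0 + o), (29.0, 8.0 + o)],
                                    line_width_px=1)
                 for o in (-1.0, 0.0, 1.0)]
        np.testing.assert_allclose(wide, np.mean(parts, axis=0), atol=1e-12)

    def test_polyline_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="exits"):
            kinetics.kymograph(self._stack(np.zeros((2, 8, 8))),
                               [(0, 0), (20, 0)])
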