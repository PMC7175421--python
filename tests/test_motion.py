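"""Tests of MSD analysis, motion-state segmentation and angle statistics."""

import numpy as np
import pytest

from myofil import motion
from myofil.simulate import BOLTZMANN_PN_NM_PER_K


def brownian(rng, n, D, dt):
    steps = rng.normal(0, np.sqrt(2 * D * dt), (n - 1, 2))
    return np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])


class TestMSD:
    def test_static_point(self):
        curve = motion.msd(np.zeros((20, 2)), 0.2)
        np.testing.assert_array_equal(curve.msd_um2, 0.0)

    def test_ballistic_closed_form(self):
        t = np.arange(50) * 0.2
        xy = np.column_stack([0.2 * t, np.zeros_like(t)])
        curve = motion.msd(xy, 0.2)
        np.testing.assert_allclose(curve.msd_um2, 0.04 * curve.lags_s ** 2,
                                   rtol=1e-10)

    def test_free_diffusion_magnitude(self):
        # 100 trajectories at D = 0.005: ensemble MSD(5 s) = 0.1 um^2
        rng = np.random.default_rng(0)
        trajs = [brownian(rng, 60, 0.005, 0.5) for _ in range(100)]
        curve = motion.ensemble_msd(trajs, 0.5)
        i = np.argmin(np.abs(curve.lags_s - 5.0))
        assert curve.msd_um2[i] == pytest.approx(4 * 0.005 * 5, rel=0.15)

    def test_pair_counts(self):
        curve = motion.msd(np.zeros((10, 2)), 1.0)
        np.testing.assert_array_equal(curve.n_pairs, np.arange(9, 0, -1))


class TestMSDComponents:
    def test_components_sum_to_total_exactly(self):
        rng = np.random.default_rng(1)
        xy = brownian(rng, 200, 0.01, 0.2)
        theta = rng.uniform(0, np.pi, 200)
        par, per = motion.msd_components(xy, theta, 0.2)
        total = motion.msd(xy, 0.2)
        np.testing.assert_allclose(par.msd_um2 + per.msd_um2, total.msd_um2,
                                   rtol=1e-9)

    def test_motion_along_fixed_axis_has_zero_perpendicular(self):
        t = np.arange(30) * 0.2
        theta = np.full(30, 0.7)
        xy = np.column_stack([np.cos(0.7) * 0.3 * t, np.sin(0.7) * 0.3 * t])
        par, per = motion.msd_components(xy, theta, 0.2)
        np.testing.assert_allclose(per.msd_um2, 0.0, atol=1e-12)
        assert par.msd_um2[0] > 0

    def test_isotropic_diffusion_splits_evenly(self):
        rng = np.random.default_rng(2)
        xy = brownian(rng, 3000, 0.01, 0.2)
        theta = np.full(3000, 1.2)
        par, per = motion.msd_components(xy, theta, 0.2, max_lag_s=0.6)
        assert par.msd_um2[0] == pytest.approx(per.msd_um2[0], rel=0.1)


class TestLogSlope:
    def test_diffusive_and_ballistic_slopes(self):
        lags = np.linspace(0.2, 20, 100)
        diff = motion.MSDCurve(lags, 4 * 0.01 * lags, np.ones(100, int))
        ball = motion.MSDCurve(lags, 0.04 * lags ** 2, np.ones(100, int))
        assert motion.log_slope(diff, (5, 10)) == pytest.approx(1.0, abs=1e-9)
        assert motion.log_slope(ball, (5, 10)) == pytest.approx(2.0, abs=1e-9)

    def test_too_few_lags_rejected(self):
        curve = motion.MSDCurve(np.array([1.0]), np.array([0.1]),
                                np.array([5]))
        with pytest.raises(ValueError):
            motion.log_slope(curve, (5, 10))


class TestEnsembleDiffusivity:
    def test_recovers_generator_diffusivity(self):
        rng = np.random.default_rng(3)
        trajs = [brownian(rng, 100, 0.01, 0.2) for _ in range(100)]
        D = motion.ensemble_diffusivity(trajs, 0.2)
        assert 0.008 <= D <= 0.012

    def test_static_tracks_give_zero(self):
        trajs = [np.zeros((50, 2)) for _ in range(10)]
        assert motion.ensemble_diffusivity(trajs, 0.2) == pytest.approx(0.0)

    def test_directed_contamination_bias_bounded_by_oracle(self):
        # 10% ballistic tracks at speed v: the ensemble MSD becomes
        # 0.9*4*D*t + 0.1*v^2*t^2, so the fitted slope over the first lags
        # bounds the bias; assert D_hat sits between D and the oracle fit
        rng = np.random.default_rng(4)
        D, v, dt = 0.01, 0.3, 0.2
        trajs = [brownian(rng, 100, D, dt) for _ in range(90)]
        t = np.arange(100) * dt
        for i in range(10):
            phi = rng.uniform(0, 2 * np.pi)
            trajs.append(np.column_stack([v * t * np.cos(phi),
                                          v * t * np.sin(phi)]))
        D_hat = motion.ensemble_diffusivity(trajs, dt)
        lags = np.arange(1, 6) * dt
        msd_mix = 0.9 * 4 * D * lags + 0.1 * v ** 2 * lags ** 2
        D_oracle = np.polyfit(lags, msd_mix, 1)[0] / 4
        assert D < D_hat < D_oracle * 1.2

    def test_too_few_tracks_rejected(self):
        with pytest.raises(ValueError):
            motion.ensemble_diffusivity([np.zeros((10, 2))] * 3, 0.2)


class TestClassifyMotion:
    def test_diffusion_null_false_directed_rate(self):
        # calibration oracle for the default envelope factor
        rng = np.random.default_rng(5)
        D = 0.005
        n_dir = n_tot = 0
        for _ in range(200):
            xy = brownian(rng, 60, D, 0.2)
            segs = motion.classify_motion(xy, 0.2, D_ref=D)
            n_dir += sum(s.n_frames for s in segs if s.state == "directed")
            n_tot += 60
        assert n_dir / n_tot <= 0.05

    def test_ballistic_track_one_directed_segment(self):
        t = np.arange(60) * 0.2
        xy = np.column_stack([0.46 * t, np.zeros_like(t)])
        segs = motion.classify_motion(xy, 0.2, D_ref=0.005)
        directed = [s for s in segs if s.state == "directed"]
        assert len(directed) == 1
        assert directed[0].n_frames >= 0.9 * 60
        assert directed[0].mean_speed_um_s == pytest.approx(0.46, rel=0.05)

    def test_alternating_states_frame_accuracy(self):
        # 2 s directed / 4 s random alternation, 600 tracks
        rng = np.random.default_rng(6)
        D, v, dt = 0.005, 0.46, 0.2
        n_ok = n_tot = 0
        for _ in range(600):
            xy = [np.zeros(2)]
            states = []
            for cyc in range(2):
                phi = rng.uniform(0, 2 * np.pi)
                for _ in range(10):          # 2 s directed
                    xy.append(xy[-1] + v * dt * np.array([np.cos(phi),
                                                          np.sin(phi)]))
                    states.append("directed")
                for _ in range(20):          # 4 s random
                    xy.append(xy[-1] + rng.normal(0, np.sqrt(2 * D * dt), 2))
                    states.append("random")
            xy = np.array(xy[:-1])
            states = np.array(states[:len(xy)])
            segs = motion.classify_motion(xy, dt, D_ref=D)
            pred = np.empty(len(xy), dtype=object)
            for s in segs:
                pred[s.start:s.end + 1] = s.state
            n_ok += int(np.sum(pred == states))
            n_tot += len(xy)
        assert n_ok / n_tot >= 0.85

    def test_short_track_single_flagged_random_segment(self):
        segs = motion.classify_motion(np.zeros((5, 2)), 0.2, D_ref=0.005)
        assert len(segs) == 1
        assert segs[0].state == "random" and segs[0].flagged

    def test_ratio_and_switch_counts(self):
        segs = [motion.MotionSegment(0, 0, 9, "random"),
                motion.MotionSegment(0, 10, 19, "directed"),
                motion.MotionSegment(0, 20, 29, "random")]
        assert motion.directed_time_ratio(segs) == pytest.approx(1 / 3)
        assert motion.switch_count(segs) == 2
        all_dir = [motion.MotionSegment(0, 0, 9, "directed")]
        assert motion.directed_time_ratio(all_dir) == 1.0
        assert motion.switch_count(all_dir) == 0


class TestAlphaAngles:
    def test_motion_along_axis_gives_zero_alpha(self):
        t = np.arange(30) * 0.2
        xy = np.column_stack([0.3 * t, np.zeros_like(t)])
        stats_ = motion.alpha_angles(xy, np.zeros(30))
        np.testing.assert_allclose(stats_.alpha_rad, 0.0, atol=1e-12)
        assert stats_.fwhm_deg == pytest.approx(5.0, abs=1e-9)  # one bin

    def test_gaussian_alpha_fwhm(self):
        # FWHM of a Gaussian is 2.355 sigma: sigma = 20 deg -> 47.1 deg
        rng = np.random.default_rng(7)
        n = 10_000
        theta = np.full(n + 1, 0.9)
        alpha = np.radians(rng.normal(0, 20, n))
        steps = np.column_stack([np.cos(0.9 + alpha), np.sin(0.9 + alpha)])
        xy = np.vstack([[0, 0], np.cumsum(0.1 * steps, axis=0)])
        stats_ = motion.alpha_angles(xy, theta)
        assert stats_.fwhm_deg == pytest.approx(47.1, abs=3.0)
        assert stats_.var_rad2 == pytest.approx(np.radians(20) ** 2, rel=0.05)

    def test_invariant_under_global_rotation(self):
        rng = np.random.default_rng(8)
        xy = np.cumsum(rng.normal(0, 0.1, (50, 2)), axis=0)
        theta = rng.uniform(0, np.pi, 50)
        base = motion.alpha_angles(xy, theta)
        phi = 0.77
        R = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
        rot = motion.alpha_angles(xy @ R.T, np.mod(theta + phi, np.pi))
        np.testing.assert_allclose(np.sort(rot.alpha_rad),
                                   np.sort(base.alpha_rad), atol=1e-9)

    def test_zero_length_steps_skipped(self):
        xy = np.array([[0, 0], [0, 0], [1, 0]], dtype=float)
        stats_ = motion.alpha_angles(xy, np.zeros(3))
        assert stats_.n_skipped == 1
        assert stats_.alpha_rad.size == 1


class TestTorsionalStiffness:
    def test_unit_variance_gives_kT(self):
        # k_B * 295.15 K = 4.075 pN nm
        k = motion.torsional_stiffness(1.0, 295.15)
        assert k == pytest.approx(BOLTZMANN_PN_NM_PER_K * 295.15, abs=1e-12)
        assert k == pytest.approx(4.075, abs=2e-3)

    def test_inverse_proportionality(self):
        assert motion.torsional_stiffness(0.5) == \
            pytest.approx(2 * motion.torsional_stiffness(1.0))

    @pytest.mark.parametrize("n,tol", [(10_000, 0.10), (1_000, 0.30)])
    def test_recovery_from_ou_angles(self, n, tol):
        # generator recovery at K_tor = 9 pN nm (realistic range 7.5-9.2)
        K_true = 9.0
        var = BOLTZMANN_PN_NM_PER_K * 295.15 / K_true
        rng = np.random.default_rng(9)
        # exact OU sampling of the stationary angle process
        decay = np.exp(-0.2 / 1.0)
        alpha = np.empty(n)
        alpha[0] = rng.normal(0, np.sqrt(var))
        for i in range(1, n):
            alpha[i] = alpha[i - 1] * decay + rng.normal(
                0, np.sqrt(var * (1 - decay ** 2)))
        K_hat = motion.torsional_stiffness(float(np.mean(alpha ** 2)))
        assert K_hat == pytest.approx(K_true, rel=tol)

    def test_zero_variance_flagged_infinite(self):
        with pytest.warns(UserWarning, match="infinite"):
            assert motion.torsional_stiffness(0.0) == np.inf
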