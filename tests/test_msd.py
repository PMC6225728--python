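"""MSD estimator and model-fit tests against brute-force and closed-form
oracles."""

import numpy as np
import pytest

from conftest import random_gapped_trajectory
from oracles import brute_force_msd, welch_t_test
from telotrack.models import AcquisitionConfig, Trajectory
from telotrack.msd import (MSDCurve, alpha_distribution, compare_groups,
                           compute_msd, ensemble_msd, fit_anomalous,
                           fit_confined)

UM2_PER_NM2 = 1e-6


def make_traj(frames, positions, n_total, dt=0.25, tid=0):
    return Trajectory(traj_id=tid, frames=np.asarray(frames),
                      positions=np.asarray(positions, dtype=float),
                      n_total_frames=n_total, dt=dt)


def curve_from_model(fn, n_lags=100, dt=0.25):
    lags = dt * np.arange(1, n_lags + 1)
    return MSDCurve(lags, fn(lags), np.full(n_lags, 100), dt)


class TestComputeMSD:
    def test_static_trajectory_is_zero(self):
        t = make_traj(np.arange(10), np.ones((10, 2)) * 7.0, 10)
        curve = compute_msd(t)
        assert np.all(curve.msd == 0)

    def test_uniform_motion_quadratic(self):
        n = 12
        pos = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
        t = make_traj(np.arange(n), pos, n)
        for mode in ("standard", "literal"):
            curve = compute_msd(t, mode=mode)
            lags_frames = np.round(curve.lags / t.dt).astype(int)
            np.testing.assert_allclose(curve.msd,
                                       lags_frames ** 2 * UM2_PER_NM2)

    def test_six_frame_example_against_oracle(self):
        pos = np.array([(0, 0), (1, 0), (1, 1), (3, 1), (3, 3), (4, 3)],
                       dtype=float)
        t = make_traj(np.arange(6), pos, 6)
        for mode in ("standard", "literal"):
            oracle = brute_force_msd(t.frames, pos, 6, mode=mode)
            curve = compute_msd(t, mode=mode)
            got = dict(zip(np.round(curve.lags / t.dt).astype(int),
                           curve.msd / UM2_PER_NM2))
            assert got[1] == pytest.approx(oracle[1], rel=1e-12)
            assert got[2] == pytest.approx(oracle[2], rel=1e-12)
        # frozen values from the hand-checked double loop
        assert brute_force_msd(t.frames, pos, 6, "standard")[1] == pytest.approx(2.2)
        assert brute_force_msd(t.frames, pos, 6, "literal")[1] == pytest.approx(2.5)
        assert brute_force_msd(t.frames, pos, 6, "standard")[2] == pytest.approx(5.0)

    @pytest.mark.parametrize("mode", ["standard", "literal"])
    def test_random_gapped_trajectories_match_oracle(self, rng, mode):
        for _ in range(50):
            t = random_gapped_trajectory(rng, int(rng.integers(6, 40)))
            oracle = brute_force_msd(t.frames, t.positions, t.n_total_frames,
                                     mode=mode)
            curve = compute_msd(t, mode=mode)
            got = dict(zip(np.round(curve.lags / t.dt).astype(int),
                           curve.msd / UM2_PER_NM2))
            assert set(got) == set(oracle)
            for lag in oracle:
                assert got[lag] == pytest.approx(oracle[lag], rel=1e-12, abs=1e-15)

    def test_lag_with_no_pairs_omitted(self):
        t = make_traj([0, 3], [(0.0, 0.0), (30.0, 0.0)], 4)
        curve = compute_msd(t)
        assert list(np.round(curve.lags / t.dt).astype(int)) == [3]

    def test_errors(self):
        t = make_traj(np.arange(6), np.zeros((6, 2)), 6)
        with pytest.raises(ValueError):
            compute_msd(t, max_lag_frames=6)
        with pytest.raises(ValueError):
            compute_msd(make_traj([0, 1], np.zeros((2, 2)), 2), mode="bogus")

    def test_scaling_covariance(self, rng):
        t = random_gapped_trajectory(rng, 30, min_present=10)
        c = 3.7
        t2 = make_traj(t.frames, t.positions * c, t.n_total_frames)
        np.testing.assert_allclose(compute_msd(t2).msd,
                                   compute_msd(t).msd * c ** 2, rtol=1e-12)

    def test_time_relabeling_leaves_msd_values_unchanged(self, rng):
        t = random_gapped_trajectory(rng, 30, min_present=10)
        t2 = make_traj(t.frames, t.positions, t.n_total_frames, dt=2 * t.dt)
        np.testing.assert_allclose(compute_msd(t2).msd, compute_msd(t).msd)


class TestEnsembleMSD:
    def test_identical_curves(self):
        t = make_traj(np.arange(8), np.cumsum(np.ones((8, 2)), axis=0), 8)
        c = compute_msd(t)
        ens = ensemble_msd([c, c, c])
        np.testing.assert_allclose(ens.msd, c.msd)
        np.testing.assert_allclose(ens.se, 0.0)

    def test_two_curve_closed_form(self):
        dt = 0.25
        c1 = MSDCurve(np.array([dt]), np.array([1.0]), np.array([1]), dt)
        c2 = MSDCurve(np.array([dt]), np.array([3.0]), np.array([1]), dt)
        ens = ensemble_msd([c1, c2])
        assert ens.msd[0] == pytest.approx(2.0)
        assert ens.se[0] == pytest.approx(1.0)  # SD sqrt(2) / sqrt(2)

    def test_mixed_dt_rejected(self):
        c1 = MSDCurve(np.array([0.25]), np.array([1.0]), np.array([1]), 0.25)
        c2 = MSDCurve(np.array([0.5]), np.array([1.0]), np.array([1]), 0.5)
        with pytest.raises(ValueError):
            ensemble_msd([c1, c2])

    def test_fbm_ensemble_matches_generator_closed_form(self):
        from telotrack.pipeline import truth_to_trajectories
        from telotrack.simulate import simulate_fbm
        acq = AcquisitionConfig(n_frames=64)
        d_alpha, alpha = 0.01, 0.4
        truth = simulate_fbm(1000, acq, d_alpha, alpha, seed=51)
        curves = [compute_msd(t) for t in truth_to_trajectories(truth)]
        ens = ensemble_msd(curves)
        want = 4 * d_alpha * ens.lags ** alpha
        for k in range(10):
            assert abs(ens.msd[k] - want[k]) < 3 * ens.se[k], f"lag {k + 1}"

    def test_lags_with_single_curve_omitted(self):
        dt = 0.25
        c1 = MSDCurve(dt * np.arange(1, 4), np.ones(3), np.ones(3, int), dt)
        c2 = MSDCurve(dt * np.arange(1, 3), np.ones(2), np.ones(2, int), dt)
        ens = ensemble_msd([c1, c2])
        assert len(ens.lags) == 2


class TestFitAnomalous:
    def test_noiseless_brownian_curve(self):
        fit = fit_anomalous(curve_from_model(lambda t: 4.0 * 1.0 * t))
        assert fit.D_alpha == pytest.approx(1.0, rel=1e-8)
        assert fit.alpha == pytest.approx(1.0, rel=1e-8)

    def test_noiseless_liver_exponent(self):
        # exponent 0.18, the subdiffusive regime of interest
        fit = fit_anomalous(curve_from_model(lambda t: 4.0 * 0.01 * t ** 0.18))
        assert fit.alpha == pytest.approx(0.18, abs=1e-6)
        assert fit.D_alpha == pytest.approx(0.01, rel=1e-5)

    def test_all_zero_curve_is_an_error(self):
        with pytest.raises(ValueError):
            fit_anomalous(curve_from_model(lambda t: 0.0 * t))

    def test_too_few_lags_rejected(self):
        c = curve_from_model(lambda t: 4 * t, n_lags=3)
        with pytest.raises(ValueError):
            fit_anomalous(c)

    def test_single_trajectory_scatter_mean_recovery(self):
        from telotrack.pipeline import recover_alpha
        acq = AcquisitionConfig(n_frames=480)
        alphas = recover_alpha(0.5, 150, acq, seed=52)
        assert alphas.std(ddof=1) > 0.02          # per-trajectory scatter
        se = alphas.std(ddof=1) / np.sqrt(len(alphas))
        assert abs(alphas.mean() - 0.5) < max(0.03, 3 * se)

    def test_scaling_leaves_alpha_invariant(self, rng):
        t = random_gapped_trajectory(rng, 120, min_present=100)
        c = 5.0
        t2 = Trajectory(0, t.frames, t.positions * c, t.n_total_frames, t.dt)
        f1 = fit_anomalous(compute_msd(t))
        f2 = fit_anomalous(compute_msd(t2))
        assert f2.alpha == pytest.approx(f1.alpha, abs=1e-6)
        assert f2.D_alpha == pytest.approx(f1.D_alpha * c ** 2, rel=1e-4)


class TestFitConfined:
    def test_noiseless_exact_recovery_and_derived_terms(self):
        a, tau = 0.04, 2.0
        fit = fit_confined(curve_from_model(
            lambda t: a * (1 - np.exp(-t / tau))))
        assert fit.A == pytest.approx(a, rel=1e-6)
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.D_macro == pytest.approx(0.0, abs=1e-9)
        assert fit.L == pytest.approx(np.sqrt(a / 2.0), rel=1e-6)
        assert fit.L == pytest.approx(0.1414, abs=5e-4)
        assert fit.D_micro == pytest.approx(a / (4 * tau), rel=1e-6)

    def test_full_model_recovery(self):
        a, tau, dm = 0.04, 2.0, 1e-4
        fit = fit_confined(curve_from_model(
            lambda t: a * (1 - np.exp(-t / tau)) + 4 * dm * t))
        assert fit.A == pytest.approx(a, rel=1e-6)
        assert fit.tau == pytest.approx(tau, rel=1e-6)
        assert fit.D_macro == pytest.approx(dm, rel=1e-5)

    def test_pure_linear_curve_degenerates_to_brownian(self):
        d = 0.005
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_confined(curve_from_model(lambda t: 4 * d * t))
        assert fit.D_macro == pytest.approx(d, rel=1e-4)
        assert fit.A < 1e-6

    def test_model_nesting_vs_anomalous(self):
        # Brownian data: confined fit's D_macro ~ anomalous fit's D at alpha=1
        from telotrack.pipeline import truth_to_trajectories
        from telotrack.simulate import simulate_brownian
        acq = AcquisitionConfig(n_frames=128)
        truth = simulate_brownian(1000, acq, 0.01, seed=53)
        curves = [compute_msd(t) for t in truth_to_trajectories(truth)]
        ens = ensemble_msd(curves)
        with pytest.warns(UserWarning):
            fc = fit_confined(ens)
        fa = fit_anomalous(ens)
        assert fc.D_macro == pytest.approx(fa.D_alpha, rel=0.05)


class TestAlphaDistribution:
    @staticmethod
    def _fits(alphas):
        from telotrack.msd import AnomalousFit
        return [AnomalousFit(0.01, a, 0.0, 10) for a in alphas]

    def test_single_fit_group(self):
        out = alpha_distribution(self._fits([0.3]), ["g"])
        assert out["g"]["mean"] == pytest.approx(0.3)
        assert out["g"]["se"] is None

    def test_groups_well_separated(self):
        from telotrack.pipeline import recover_alpha
        acq = AcquisitionConfig(n_frames=240)
        a = recover_alpha(0.18, 100, acq, seed=54)
        b = recover_alpha(0.5, 100, acq, seed=55)
        out = alpha_distribution(self._fits(np.concatenate([a, b])),
                                 ["liver"] * 100 + ["culture"] * 100)
        pooled_se = np.hypot(out["liver"]["se"], out["culture"]["se"])
        assert out["culture"]["mean"] - out["liver"]["mean"] > 5 * pooled_se

    def test_label_permutation_invariance(self, rng):
        alphas = rng.uniform(0.1, 1.9, 40)
        labels = list(rng.integers(0, 3, 40))
        order = rng.permutation(40)
        out1 = alpha_distribution(self._fits(alphas), labels)
        out2 = alpha_distribution(self._fits(alphas[order]),
                                  [labels[i] for i in order])
        for g in out1:
            assert out1[g]["mean"] == pytest.approx(out2[g]["mean"])
            np.testing.assert_array_equal(out1[g]["hist"], out2[g]["hist"])

    def test_histogram_bins_fixed(self):
        out = alpha_distribution(self._fits([0.05, 0.15, 0.15]), [1, 1, 1])
        assert len(out[1]["hist"]) == 20
        assert out[1]["hist"][0] == 1 and out[1]["hist"][1] == 2


class TestCompareGroups:
    def test_identical_groups(self):
        t, df, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_welch_oracle(self):
        a, b = [0, 0, 0, 1], [3, 4, 3, 4]
        t, df, p = compare_groups(a, b)
        t_o, df_o, p_o = welch_t_test(a, b)
        assert t == pytest.approx(t_o, rel=1e-10)
        assert df == pytest.approx(df_o, rel=1e-10)
        assert p == pytest.approx(p_o, rel=1e-10)

    def test_swap_symmetry(self):
        a, b = [0.1, 0.5, 0.2], [0.9, 1.3, 1.1]
        t1, _, p1 = compare_groups(a, b)
        t2, _, p2 = compare_groups(b, a)
        assert t2 == pytest.approx(-t1)
        assert p2 == pytest.approx(p1)

    def test_zero_variance_equal_means(self):
        t, _, p = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
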