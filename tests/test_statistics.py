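import numpy as np
import pytest

import hetmig as hm
from hetmig import statistics as stats

from _reference import (
    naive_G,
    naive_accel_samples,
    naive_gi,
    naive_msd,
    naive_vacf,
)


class TestVelocities:
    def test_hand_computed_velocity(self, three_point_cell):
        _, v = hm.velocities(three_point_cell)[0]
        np.testing.assert_allclose(v[0], [3 / 34, 4 / 34])
        assert np.hypot(*v[0]) == pytest.approx(5 / 34)

    def test_static_and_linear_motion(self):
        t = np.arange(5) * 34.0
        static = hm.TrajectoryTable.from_positions(t, np.zeros((1, 5, 2)))
        _, v = hm.velocities(static)[0]
        assert np.all(v == 0.0)
        linear = hm.TrajectoryTable.from_positions(
            t, (t[:, None] * np.array([0.25, -0.1]))[None]
        )
        _, v = hm.velocities(linear)[0]
        np.testing.assert_allclose(v, np.tile([0.25, -0.1], (4, 1)))

    def test_incommensurate_dt_rejected(self, three_point_cell):
        with pytest.raises(ValueError, match="not a multiple"):
            hm.velocities(three_point_cell, dt=40.0)


class TestMSD:
    def test_hand_computed_example(self, three_point_cell):
        curve = hm.msd(three_point_cell, [34.0, 68.0])
        np.testing.assert_allclose(curve.values, [25.0, 100.0])

    def test_static_cohort_is_zero(self):
        static = hm.TrajectoryTable.from_positions(
            np.arange(4) * 34.0, np.zeros((3, 4, 2))
        )
        assert np.all(hm.msd(static, [34.0, 68.0]).values == 0.0)

    def test_lag_beyond_duration_rejected(self, three_point_cell):
        with pytest.raises(ValueError, match="duration"):
            hm.msd(three_point_cell, [340.0])

    def test_fast_and_slow_paths_agree(self, small_random_cohort):
        mixed = hm.TrajectoryTable(
            dict(small_random_cohort.data,
                 extra=(np.arange(3) * 68.0, np.ones((3, 2))))
        )
        lags = [68.0]
        np.testing.assert_allclose(
            hm.msd(small_random_cohort, lags).values, naive_msd(small_random_cohort, lags)
        )
        np.testing.assert_allclose(hm.msd(mixed, lags).values, naive_msd(mixed, lags))


class TestSelfCorrelation:
    def test_static_cell_mass_in_first_bin(self):
        static = hm.TrajectoryTable.from_positions(
            np.arange(5) * 34.0, np.zeros((1, 5, 2))
        )
        curve = hm.self_correlation_single(static, 0, 34.0, np.arange(5) * 2.5)
        assert curve.densities[0] > 0 and np.all(curve.densities[1:] == 0)
        assert curve.normalization() == pytest.approx(1.0, abs=1e-9)

    def test_three_point_mass_at_five_microns(self, three_point_cell):
        edges = np.arange(5) * 2.5
        curve = hm.self_correlation_single(three_point_cell, 0, 34.0, edges)
        probs = curve.densities * np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
        assert probs[2] == pytest.approx(1.0)  # bin [5.0, 7.5) holds r = 5
        assert curve.normalization() == pytest.approx(1.0, abs=1e-12)

    def test_ensemble_equals_pooled_for_equal_origin_counts(self):
        rng = np.random.default_rng(0)
        traj = hm.TrajectoryTable.from_positions(
            np.arange(6) * 34.0, rng.normal(0, 5, (4, 6, 2)).cumsum(axis=1)
        )
        edges = stats.default_bin_edges(
            hm.displacements(traj, 68.0).max(), 2.5
        )
        ens = hm.self_correlation_ensemble(traj, 68.0, edges)
        pooled = stats._radial_density(hm.displacements(traj, 68.0), edges)
        np.testing.assert_allclose(ens.densities, pooled, atol=1e-12)

    def test_single_cell_ensemble_identity(self, three_point_cell):
        edges = np.arange(5) * 2.5
        a = hm.self_correlation_single(three_point_cell, 0, 34.0, edges)
        b = hm.self_correlation_ensemble(three_point_cell, 34.0, edges)
        np.testing.assert_array_equal(a.densities, b.densities)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_normalization_invariant(self, seed):
        rng = np.random.default_rng(seed)
        traj = hm.TrajectoryTable.from_positions(
            np.arange(8) * 34.0, rng.normal(0, 8, (5, 8, 2)).cumsum(axis=1)
        )
        edges = stats.default_bin_edges(hm.displacements(traj, 34.0).max())
        curve = hm.self_correlation_ensemble(traj, 34.0, edges)
        assert curve.normalization() == pytest.approx(1.0, abs=1e-6)

    def test_ho_cohort_is_gaussian(self, ho_velocity_cohort):
        """G(r, t) of a homogeneous PRW cohort matches the 2-D Gaussian law."""
        _, traj, _ = ho_velocity_cohort
        lag = 68.0
        mags = hm.displacements(traj, lag)
        edges = stats.default_bin_edges(mags.max(), 1.0)
        G = hm.self_correlation_ensemble(traj, lag, edges)
        msd_val = hm.msd(traj, [lag]).values[0]
        ref = hm.gaussian_reference(lag, msd_val, edges)
        assert np.max(np.abs(G.densities - ref.densities)) < 0.03 * ref.densities.max()


class TestGaussianReference:
    def test_known_value_at_origin(self):
        curve = hm.gaussian_reference(68.0, 100.0, np.array([0.0, 1e-6]))
        assert curve.densities[0] == pytest.approx(1.0 / (100 * np.pi), rel=1e-6)

    def test_normalized_over_fine_bins(self):
        edges = np.linspace(0, 80, 4001)
        curve = hm.gaussian_reference(68.0, 100.0, edges)
        assert curve.normalization() == pytest.approx(1.0, abs=1e-4)

    def test_nonpositive_msd_rejected(self):
        with pytest.raises(ValueError):
            hm.gaussian_reference(68.0, 0.0, np.array([0.0, 1.0]))


class TestRescaledCurves:
    def test_gaussian_cells_collapse_onto_exp(self):
        """Gaussian g_i with different r* all rescale onto exp(−u²)."""
        edges = np.linspace(0, 60, 600)
        curves, r_stars = [], {}
        for cid, msd_val in enumerate([25.0, 100.0, 400.0]):
            g = hm.gaussian_reference(68.0, msd_val, edges)
            g.cell_id = cid
            curves.append(g)
            r_stars[cid] = np.sqrt(msd_val)
        rescaled = hm.rescale_correlation(curves, r_stars, x_bin_width=0.25)
        keep = rescaled.x_centers < 2.0
        expected = np.exp(-rescaled.x_centers[keep] ** 2)
        assert np.max(np.abs(rescaled.mean[keep] - expected)) < 0.02

    def test_single_cell_sem_zero(self):
        edges = np.linspace(0, 30, 100)
        g = hm.gaussian_reference(68.0, 25.0, edges)
        g.cell_id = 0
        rescaled = hm.rescale_correlation([g], {0: 5.0})
        assert np.all(rescaled.sem[rescaled.counts > 1] >= 0)
        assert np.all(rescaled.sem[rescaled.counts == 1] == 0)

    def test_zero_rstar_excluded_with_warning(self):
        edges = np.linspace(0, 30, 100)
        good = hm.gaussian_reference(68.0, 25.0, edges)
        good.cell_id = 0
        bad = hm.gaussian_reference(68.0, 25.0, edges)
        bad.cell_id = 1
        with pytest.warns(UserWarning, match="r\\* = 0"):
            hm.rescale_correlation([good, bad], {0: 5.0, 1: 0.0})


class TestVACF:
    def test_straight_line_is_one(self):
        t = np.arange(6) * 34.0
        traj = hm.TrajectoryTable.from_positions(
            t, (t[:, None] * np.array([0.2, 0.1]))[None]
        )
        _, vals = hm.vacf(traj, 0)
        np.testing.assert_allclose(vals, 1.0)

    def test_zigzag_is_minus_one_at_one_step(self):
        xy = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 0.0], [5.0, 0.0], [0.0, 0.0]])
        traj = hm.TrajectoryTable({0: (np.arange(5) * 34.0, xy)})
        _, vals = hm.vacf(traj, 0)
        assert vals[1] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        static = hm.TrajectoryTable.from_positions(np.arange(4) * 34.0,
                                                   np.zeros((1, 4, 2)))
        with pytest.raises(ValueError, match="zero-variance"):
            hm.vacf(static, 0)


class TestAcceleration:
    def test_constant_velocity_zero_acceleration(self):
        t = np.arange(6) * 34.0
        traj = hm.TrajectoryTable.from_positions(
            t, (t[:, None] * np.array([0.2, 0.0]))[None]
        )
        acc = hm.acceleration_stats(traj)
        np.testing.assert_allclose(acc.mean_ap, 0.0, atol=1e-15)
        np.testing.assert_allclose(acc.mean_anp, 0.0, atol=1e-15)

    def test_hand_computed_right_turn(self):
        """v = (1,0) → (0,1) μm/min: a_p = −1/34, a_np = +1/34."""
        xy = np.array([[0.0, 0.0], [34.0, 0.0], [34.0, 34.0]])
        traj = hm.TrajectoryTable({0: (np.arange(3) * 34.0, xy)})
        acc = hm.acceleration_stats(traj, speed_bin_width=0.5)
        assert acc.mean_ap[-1] == pytest.approx(-1 / 34)
        assert acc.mean_anp[-1] == pytest.approx(1 / 34)

    def test_ho_cohort_follows_velocity_relaxation(self, ho_velocity_cohort):
        """⟨a_p⟩_v is linear in v with the finite-difference OU slope; ⟨a_np⟩_v ≈ 0."""
        params, traj, _ = ho_velocity_cohort
        acc = hm.acceleration_stats(traj).filtered(100)
        w = acc.counts
        slope = np.sum(w * acc.speed_centers * acc.mean_ap) / np.sum(
            w * acc.speed_centers**2
        )
        # closed form for secant velocities: slope = -(1-rho)/dt with
        # rho = (1-a)^2 / (2(a + h/P - 1)), a = exp(-h/P)
        h, P = 34.0, params.P
        a = np.exp(-h / P)
        rho = (1 - a) ** 2 / (2 * (a + h / P - 1))
        expected = -(1 - rho) / h
        assert slope == pytest.approx(expected, rel=0.05)
        assert np.max(np.abs(acc.mean_anp)) < 5e-4


class TestOracleEquivalence:
    """All statistics agree exactly with naive double-loop references."""

    def test_msd(self, small_random_cohort):
        lags = [34.0, 68.0, 102.0]
        np.testing.assert_allclose(
            hm.msd(small_random_cohort, lags).values,
            naive_msd(small_random_cohort, lags), rtol=1e-12,
        )

    def test_van_hove(self, small_random_cohort):
        edges = stats.default_bin_edges(
            hm.displacements(small_random_cohort, 68.0).max(), 2.5
        )
        for cid in small_random_cohort.cell_ids:
            np.testing.assert_allclose(
                hm.self_correlation_single(small_random_cohort, cid, 68.0, edges).densities,
                naive_gi(small_random_cohort, cid, 68.0, edges), rtol=1e-12,
            )
        np.testing.assert_allclose(
            hm.self_correlation_ensemble(small_random_cohort, 68.0, edges).densities,
            naive_G(small_random_cohort, 68.0, edges), rtol=1e-12,
        )

    def test_vacf(self, small_random_cohort):
        for cid in small_random_cohort.cell_ids:
            _, v = hm.velocities(small_random_cohort)[cid]
            np.testing.assert_allclose(
                hm.vacf(small_random_cohort, cid)[1], naive_vacf(v), rtol=1e-12
            )

    def test_acceleration(self, small_random_cohort):
        ref = naive_accel_samples(small_random_cohort)
        acc = hm.acceleration_stats(small_random_cohort, speed_bin_width=1e9)
        # one giant speed bin: conditional means equal plain means
        assert acc.mean_ap[0] == pytest.approx(ref[:, 1].mean(), rel=1e-12)
        assert acc.mean_anp[0] == pytest.approx(ref[:, 2].mean(), rel=1e-12)
        assert acc.counts[0] == ref.shape[0]

    def test_msd_second_moment_consistency(self, small_random_cohort):
        """MSD equals the second moment of the displacement histogram's samples."""
        lag = 68.0
        mags = hm.displacements(small_random_cohort, lag)
        per_cell = [
            np.mean(hm.displacements(small_random_cohort, lag, scope=c) ** 2)
            for c in small_random_cohort.cell_ids
        ]
        assert hm.msd(small_random_cohort, [lag]).values[0] == pytest.approx(
            np.mean(per_cell), rel=1e-12
        )
        assert mags.min() >= 0
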