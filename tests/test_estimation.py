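import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ks_2samp

import hetmig as hm
from hetmig import estimation as est
from hetmig import simulate as sim
from hetmig import statistics as stats
from hetmig.estimation import _first_crossing


class TestAnalyticMSD:
    def test_zero_lag_is_noise_floor(self):
        assert hm.eval_prw_msd(0.125, 78.0, 1.66, 0.0) == pytest.approx(4 * 1.66**2)

    def test_worked_value_at_one_persistence_time(self):
        val = hm.eval_prw_msd(0.125, 78.0, 1.66, 78.0)
        expected = 2 * 0.125**2 * 78.0**2 * np.exp(-1.0) + 4 * 1.66**2
        assert val == pytest.approx(expected)
        assert val == pytest.approx(80.97, abs=0.01)

    def test_fickian_long_time_slope(self):
        S, P = 0.125, 78.0
        t = 1e4 * P
        slope = (hm.eval_prw_msd(S, P, 0.0, t + 1.0) - hm.eval_prw_msd(S, P, 0.0, t))
        assert slope == pytest.approx(2 * S**2 * P, rel=1e-3)

    def test_nonpositive_persistence_rejected(self):
        with pytest.raises(ValueError):
            hm.eval_prw_msd(0.1, 0.0, 0.0, 10.0)


class TestPRWFit:
    @pytest.mark.parametrize("S", [0.05, 0.125, 0.3])
    @pytest.mark.parametrize("P", [30.0, 78.0, 150.0])
    @pytest.mark.parametrize("sig", [0.5, 1.66, 3.0])
    def test_exact_on_noise_free_curves(self, S, P, sig):
        lags = np.arange(1, 39) * 34.0
        curve = stats.MSDCurve(lags, hm.eval_prw_msd(S, P, sig, lags),
                               np.zeros_like(lags), np.full(lags.size, 1))
        fit = hm.fit_prw_msd(curve)
        assert fit.S == pytest.approx(S, rel=1e-6)
        assert fit.P == pytest.approx(P, rel=1e-6)
        assert fit.sigma_err == pytest.approx(sig, rel=1e-6)

    def test_excluding_first_lag_is_robust(self):
        """Dropping the t = 34 min point shifts parameters by less than their SE."""
        traj = hm.simulate_ho(hm.HOParams(S=0.125, P=78.0, integration_dt=0.1),
                              500, 1292.0, seed=21)
        noisy = hm.add_localization_error(traj, 1.66, seed=22)
        curve = hm.msd(noisy, np.arange(1, 39) * 34.0)
        full = hm.fit_prw_msd(curve)
        trimmed = hm.fit_prw_msd(curve, exclude_lags=[34.0])
        rel_shift = np.abs(full.params - trimmed.params) / full.params
        assert rel_shift[0] < 0.05  # S
        assert rel_shift[1] < 0.05  # P
        assert rel_shift[2] < 0.10  # sigma_err, set mostly by the shortest lags

    def test_too_few_lags_rejected(self):
        lags = np.arange(1, 4) * 34.0
        curve = stats.MSDCurve(lags, hm.eval_prw_msd(0.1, 50.0, 1.0, lags),
                               np.zeros_like(lags), np.full(lags.size, 1))
        with pytest.raises(ValueError, match="at least 4"):
            hm.fit_prw_msd(curve)


class TestDiscretizePersistence:
    def test_printed_mapping(self):
        assert hm.discretize_persistence(78.0, 34.0) == 68.0

    def test_exact_multiple_unchanged(self):
        assert hm.discretize_persistence(34.0, 34.0) == 34.0

    def test_interpolated_crossing_example(self):
        assert hm.discretize_persistence(51.97, 34.0) == 68.0

    @given(P=st.floats(0.01, 5000.0), dt=st.sampled_from([2.0, 34.0, 68.0]))
    @settings(max_examples=200, deadline=None)
    def test_always_positive_grid_multiple(self, P, dt):
        out = hm.discretize_persistence(P, dt)
        assert out >= dt
        assert (out / dt) == int(out / dt)


class TestPerCellEstimation:
    def test_interpolated_crossing_value(self):
        lags = np.array([0.0, 34.0, 68.0])
        vals = np.array([1.0, 0.5, 0.25])
        crossing = _first_crossing(lags, vals, est.E_INV)
        expected = 34.0 + 34.0 * (0.5 - np.exp(-1)) / (0.5 - 0.25)
        assert crossing == pytest.approx(expected)
        assert crossing == pytest.approx(51.97, abs=0.01)
        assert hm.discretize_persistence(crossing, 34.0) == 68.0

    def test_constant_velocity_cell_flagged(self):
        t = np.arange(6) * 34.0
        traj = hm.TrajectoryTable.from_positions(
            t, (t[:, None] * np.array([0.2, 0.1]))[None]
        )
        out = hm.estimate_percell(traj)
        assert out.flagged[0]
        assert out.P_cont[0] == pytest.approx(4 * 34.0)

    def test_recovery_on_homogeneous_cohort(self):
        """Median P_i and mean S_i track the generating OU parameters.

        Finite-difference velocities at 34-min sampling decorrelate more
        slowly than the OU states, so the VACF-crossing P_i overshoots P, and
        the mean secant speed sits below S by the Rayleigh-mean and secant
        attenuation factors; both predictions are closed forms.
        """
        traj = hm.simulate_ho(hm.HOParams(S=0.125, P=78.0, integration_dt=0.1),
                              400, 1292.0, seed=31)
        out = hm.estimate_percell(traj)
        assert abs(np.median(out.P_cont) - 78.0) / 78.0 < 0.25
        msd34 = hm.eval_prw_msd(0.125, 78.0, 0.0, 34.0)
        predicted_mean_speed = np.sqrt(msd34 / (2 * 34.0**2)) * np.sqrt(np.pi / 2)
        assert out.S_i.mean() == pytest.approx(predicted_mean_speed, rel=0.05)
        assert np.all(out.P_disc % 34.0 == 0.0)


class TestDisplacementSampler:
    def test_degenerate_source_returns_constant(self):
        sampler = est.DisplacementSampler(np.full(10, 7.5), lag=68.0, seed=0)
        assert np.all(sampler.draw(100) == 7.5)
        assert np.all(sampler.ppf([0.0, 0.5, 1.0]) == 7.5)

    @given(seed=st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_draws_within_source_range_and_cdf_monotone(self, seed):
        rng = np.random.default_rng(seed)
        mags = rng.lognormal(1.0, 0.6, 50)
        sampler = est.DisplacementSampler(mags, lag=68.0, seed=seed)
        draws = sampler.draw(200)
        assert draws.min() >= mags.min() and draws.max() <= mags.max()
        u = np.linspace(0, 1, 101)
        assert np.all(np.diff(sampler.ppf(u)) >= 0)

    def test_deterministic_given_seed(self):
        mags = np.random.default_rng(3).rayleigh(5.0, 100)
        a = est.DisplacementSampler(mags, 68.0, seed=11).draw(50)
        b = est.DisplacementSampler(mags, 68.0, seed=11).draw(50)
        assert np.array_equal(a, b)

    def test_inverse_transform_reproduces_source_distribution(self):
        rng = np.random.default_rng(4)
        source = rng.lognormal(1.5, 0.5, 1000)
        sampler = est.DisplacementSampler(source, 68.0, seed=5)
        draws = sampler.draw(10_000)
        assert ks_2samp(draws, source).pvalue > 0.01

    def test_sampler_from_ho_cohort_matches_rayleigh_moments(self):
        """Draws at lag P reproduce the OU displacement law's moments."""
        traj = hm.simulate_ho(hm.HOParams(S=0.125, P=78.0, integration_dt=0.1),
                              300, 1292.0, seed=41)
        sampler = hm.build_displacement_sampler(traj, 68.0, seed=6)
        draws = sampler.draw(20_000)
        m2 = hm.eval_prw_msd(0.125, 78.0, 0.0, 68.0)
        assert np.mean(draws**2) == pytest.approx(m2, rel=0.1)
        # Rayleigh mean = sqrt(pi/4 * <r^2>)
        assert np.mean(draws) == pytest.approx(np.sqrt(np.pi / 4 * m2), rel=0.1)

    def test_empty_scope_rejected(self, three_point_cell):
        with pytest.raises(ValueError):
            hm.build_displacement_sampler(three_point_cell, 40.0, scope=0)


class TestMemoryCalibration:
    def test_iid_reference_drives_memory_out(self):
        """An i.i.d.-step reference calibrates to a large A and matches its MSD."""
        mags = np.random.default_rng(8).rayleigh(5.0, 400)
        sampler = est.DisplacementSampler(mags, 68.0)
        ref = sim.simulate_th(sim.THParams(1e12, sampler, 400, 1292.0, 68.0), seed=51)
        ref_msd = hm.msd(ref, np.arange(1, 20) * 68.0)
        # memory inflates MSD by ~2/A, so the search range must extend well
        # beyond the default persistent regime to represent i.i.d. steps
        cal = hm.calibrate_memory(ref_msd, sampler, 68.0, model="th", n_cells=400,
                                  duration=1292.0, n_replicates=20, seed=52,
                                  bounds=(1.01, 500.0))
        assert cal.A > 50.0
        check = np.mean(
            [hm.msd(sim.simulate_th(sim.THParams(cal.A, sampler, 400, 1292.0, 68.0),
                                    seed=60 + r), ref_msd.lags).values
             for r in range(20)], axis=0,
        )
        assert np.max(np.abs(check / ref_msd.values - 1.0)) < 0.05

    def test_unusable_reference_rejected(self):
        curve = stats.MSDCurve(np.array([10.0]), np.array([1.0]),
                               np.array([0.1]), np.array([5]))
        sampler = est.DisplacementSampler(np.full(5, 2.0), 68.0)
        with pytest.raises(ValueError, match="fewer than 2"):
            hm.calibrate_memory(curve, sampler, 68.0, model="th", n_cells=10,
                                duration=1292.0, n_replicates=2, seed=0)
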