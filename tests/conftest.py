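import numpy as np
import pytest

import hetmig as hm


@pytest.fixture(scope="session")
def ho_velocity_cohort():
    """Large homogeneous PRW cohort with exact OU velocity states.

    10⁴ cells at the canonical design (S = 0.125 μm/min, P = 78 min,
    τ = 1292 min, 34-min sampling) — big enough for the closed-form checks of
    the OU stationary law, the VACF decay and the acceleration decomposition.
    """
    params = hm.HOParams(S=0.125, P=78.0, integration_dt=0.1)
    traj, vel = hm.simulate_ho(params, 10_000, 1292.0, seed=101, return_velocities=True)
    return params, traj, vel


@pytest.fixture(scope="session")
def small_random_cohort():
    """5 cells × 6 frames of irregular positions for oracle-equivalence tests."""
    rng = np.random.default_rng(7)
    times = np.arange(6) * 34.0
    positions = rng.normal(0.0, 12.0, size=(5, 6, 2)).cumsum(axis=1)
    return hm.TrajectoryTable.from_positions(times, positions)


@pytest.fixture
def three_point_cell():
    """The hand-computed 3-4-5 walk: (0,0) → (3,4) → (6,8) at 34-min steps."""
    times = np.array([0.0, 34.0, 68.0])
    xy = np.array([[0.0, 0.0], [3.0, 4.0], [6.0, 8.0]])
    return hm.TrajectoryTable({0: (times, xy)})
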