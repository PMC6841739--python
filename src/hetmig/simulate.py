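"""Stochastic simulators for the four migration models.

Two families of dynamics are implemented:

* **Velocity-relaxation (persistent random walk, PRW)** — each velocity
  component follows an Ornstein–Uhlenbeck process

      dv/dt = -v/P + (S/sqrt(P)) dW,

  with persistence time ``P`` (min) and speed scale ``S`` (μm/min); the
  stationary per-component variance is ``S²/2`` so the stationary mean-square
  speed is ``S²``. The homogeneous model uses one ``(S, P)`` pair for every
  cell; the cell-heterogeneous model gives cell *i* its own ``(S_i, P_i)``.
  Integration uses the exact discrete OU update

      v <- v·e^{-h/P} + sqrt((1 - e^{-2h/P})·S²/2)·N(0, 1)

  per component with step ``h`` (default 0.01 min), positions accumulated by
  Euler quadrature, and initial velocities drawn from the stationary law so
  there is no equilibration transient.

* **Step-based temporal-noise walks** — displacements on a coarse step grid
  (one step per persistence time) with a freshly sampled step magnitude β and
  a uniformly random direction at every step, plus a geometric memory of the
  previous displacement:

      dr(t + dt) = dr(t)/A + β(t)·ξ.

  β is drawn from an empirical displacement sampler (inverse-transform
  sampling of the observed step-length distribution); the memory parameter
  ``A > 1`` sets how persistent the walk is. The temporally heterogeneous
  model uses one sampler and one step length for all cells; the combined
  model gives cell *i* its own sampler and step length ``P_i``. The first
  step carries no memory term (there is no displacement before t = 0).

Localization error (position measurement noise) is added separately with
:func:`add_localization_error`, mirroring how it enters an experiment: on the
sampled positions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .trajectories import TrajectoryTable

__all__ = [
    "HOParams",
    "CHParams",
    "THParams",
    "CTHParams",
    "simulate_ho",
    "simulate_ch",
    "simulate_th",
    "simulate_cth",
    "add_localization_error",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class HOParams:
    """Homogeneous PRW parameters (one (S, P) for every cell)."""

    S: float  # μm/min
    P: float  # min
    sigma_err: float = 0.0  # μm, bookkeeping only; applied via add_localization_error
    integration_dt: float = 0.01  # min
    sampling_dt: float = 34.0  # min

    def __post_init__(self) -> None:
        if self.S < 0:
            raise ValueError(f"S must be >= 0, got {self.S}")
        if self.P <= 0:
            raise ValueError(f"P must be > 0, got {self.P}")
        if self.sigma_err < 0:
            raise ValueError(f"sigma_err must be >= 0, got {self.sigma_err}")
        if self.integration_dt <= 0:
            raise ValueError("integration_dt must be > 0")
        _stride(self.sampling_dt, self.integration_dt)  # validates commensurability


@dataclass
class CHParams:
    """Per-cell PRW parameters: arrays of S_i (μm/min) and P_i (min)."""

    S_i: np.ndarray
    P_i: np.ndarray
    sigma_err: float = 0.0
    integration_dt: float = 0.01
    sampling_dt: float = 34.0

    def __post_init__(self) -> None:
        self.S_i = np.asarray(self.S_i, dtype=float)
        self.P_i = np.asarray(self.P_i, dtype=float)
        if self.S_i.shape != self.P_i.shape or self.S_i.ndim != 1:
            raise ValueError("S_i and P_i must be 1-D arrays of equal length")
        if np.any(self.S_i < 0):
            raise ValueError("all S_i must be >= 0")
        if np.any(self.P_i <= 0):
            raise ValueError("all P_i must be > 0")
        if self.sigma_err < 0:
            raise ValueError("sigma_err must be >= 0")
        _stride(self.sampling_dt, self.integration_dt)

    @property
    def n_cells(self) -> int:
        return self.S_i.size


@dataclass
class THParams:
    """Temporal-noise walk, one sampler and step length shared by all cells."""

    A_th: float
    beta_source: object  # DisplacementSampler-like: has .ppf(u)
    n_cells: int
    duration: float  # min
    step_dt: float = 68.0  # min; the discretized persistence time

    def __post_init__(self) -> None:
        if self.A_th <= 0:
            raise ValueError(f"A_th must be > 0, got {self.A_th}")
        if self.step_dt <= 0:
            raise ValueError("step_dt must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.duration < 2 * self.step_dt:
            raise ValueError("duration must cover at least two steps")
        if not hasattr(self.beta_source, "ppf"):
            raise ValueError("beta_source must expose .ppf(u)")


@dataclass
class CTHParams:
    """Combined model: per-cell step length P_i and per-cell sampler."""

    A_cth: float
    P_i: np.ndarray  # min, one per cell
    beta_sources: Sequence  # one sampler per cell
    duration: float

    def __post_init__(self) -> None:
        self.P_i = np.asarray(self.P_i, dtype=float)
        if self.A_cth <= 0:
            raise ValueError(f"A_cth must be > 0, got {self.A_cth}")
        if len(self.beta_sources) != self.P_i.size:
            raise ValueError("need one beta sampler per cell")
        if np.any(self.P_i <= 0):
            raise ValueError("all P_i must be > 0")
        for k, s in enumerate(self.beta_sources):
            if not hasattr(s, "ppf"):
                raise ValueError(f"beta_sources[{k}] must expose .ppf(u)")
        if self.duration < 2 * float(np.min(self.P_i)):
            raise ValueError("duration must cover at least two steps of every cell")

    @property
    def n_cells(self) -> int:
        return self.P_i.size


# ---------------------------------------------------------------------------
# OU (PRW) simulators


def _stride(coarse: float, fine: float) -> int:
    stride = coarse / fine
    if abs(stride - round(stride)) > 1e-8:
        raise ValueError(f"{coarse} is not a multiple of the integration step {fine}")
    return int(round(stride))


def _simulate_ou_cell(
    rng: np.random.Generator,
    S: float,
    P: float,
    h: float,
    n_steps: int,
    sample_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact-discretization OU velocity + Euler positions for one cell.

    Returns sampled positions and sampled velocity states, shapes (n_out, 2).
    """
    a = np.exp(-h / P)
    b = np.sqrt((1.0 - a * a) * S * S / 2.0)
    v0 = rng.standard_normal(2) * np.sqrt(S * S / 2.0)
    z = rng.standard_normal((n_steps, 2))
    v = np.empty((n_steps + 1, 2))
    v[0] = v0
    # AR(1) recursion v_k = a v_{k-1} + b z_k, done in C by lfilter
    v[1:] = lfilter([1.0], [1.0, -a], b * z, axis=0, zi=(a * v0)[None, :])[0]
    pos = np.empty((n_steps + 1, 2))
    pos[0] = 0.0
    np.cumsum(v[:-1] * h, axis=0, out=pos[1:])
    return pos[sample_idx], v[sample_idx]


def _ou_table(
    S_arr: np.ndarray,
    P_arr: np.ndarray,
    h: float,
    sampling_dt: float,
    duration: float,
    seed: int,
    return_velocities: bool,
) -> TrajectoryTable | tuple[TrajectoryTable, np.ndarray]:
    if duration < 2 * sampling_dt:
        raise ValueError("duration must be at least two sampling intervals")
    stride = _stride(sampling_dt, h)
    n_frames = int(np.floor(duration / sampling_dt + 1e-9))
    n_steps = n_frames * stride
    sample_idx = np.arange(0, n_steps + 1, stride)
    times = sample_idx * h
    rng = np.random.default_rng(seed)
    n_cells = S_arr.size
    positions = np.empty((n_cells, n_frames + 1, 2))
    velocities = np.empty((n_cells, n_frames + 1, 2))
    for i in range(n_cells):
        positions[i], velocities[i] = _simulate_ou_cell(
            rng, float(S_arr[i]), float(P_arr[i]), h, n_steps, sample_idx
        )
    table = TrajectoryTable.from_positions(times, positions)
    if return_velocities:
        return table, velocities
    return table


def simulate_ho(
    params: HOParams,
    n_cells: int,
    duration: float,
    seed: int,
    return_velocities: bool = False,
):
    """Simulate ``n_cells`` independent homogeneous PRW cells.

    Positions are sampled every ``params.sampling_dt`` minutes; localization
    error is *not* applied here. With ``return_velocities=True`` the exact OU
    velocity states at the sampled times are returned alongside the table.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    S = np.full(n_cells, params.S)
    P = np.full(n_cells, params.P)
    return _ou_table(
        S, P, params.integration_dt, params.sampling_dt, duration, seed, return_velocities
    )


def simulate_ch(
    params: CHParams,
    duration: float,
    seed: int,
    return_velocities: bool = False,
):
    """Simulate one independent PRW per cell with its own (S_i, P_i)."""
    return _ou_table(
        params.S_i,
        params.P_i,
        params.integration_dt,
        params.sampling_dt,
        duration,
        seed,
        return_velocities,
    )


# ---------------------------------------------------------------------------
# step-based temporal-noise simulators


def simulate_th(params: THParams, seed: int) -> TrajectoryTable:
    """Temporal-noise walk: shared empirical step-length sampler, shared step grid.

    Randomness is consumed in a documented order (step-magnitude uniforms for
    all steps and cells, then direction uniforms), so a naive step-by-step
    reference implementation seeded identically reproduces the output
    bit-for-bit.
    """
    rng = np.random.default_rng(seed)
    n_steps = int(np.floor(params.duration / params.step_dt + 1e-9))
    n = params.n_cells
    u = rng.random((n_steps, n))
    theta = rng.random((n_steps, n)) * (2.0 * np.pi)
    beta = np.asarray(params.beta_source.ppf(u), dtype=float)
    step_x = beta * np.cos(theta)
    step_y = beta * np.sin(theta)
    disp = np.empty((n_steps, n, 2))
    prev = np.zeros((n, 2))
    for k in range(n_steps):
        if k == 0:
            prev = np.stack([step_x[0], step_y[0]], axis=1)
        else:
            prev = prev / params.A_th + np.stack([step_x[k], step_y[k]], axis=1)
        disp[k] = prev
    pos = np.empty((n_steps + 1, n, 2))
    pos[0] = 0.0
    np.cumsum(disp, axis=0, out=pos[1:])
    times = np.arange(n_steps + 1) * params.step_dt
    return TrajectoryTable.from_positions(times, np.swapaxes(pos, 0, 1))


def simulate_cth(params: CTHParams, seed: int) -> TrajectoryTable:
    """Combined walk: per-cell step length P_i and per-cell sampler.

    Cells are simulated sequentially; each cell consumes its step-magnitude
    uniforms, then its direction uniforms (documented RNG order for the naive
    reference oracle).
    """
    rng = np.random.default_rng(seed)
    data = {}
    for i in range(params.n_cells):
        step_dt = float(params.P_i[i])
        n_steps = int(np.floor(params.duration / step_dt + 1e-9))
        u = rng.random(n_steps)
        theta = rng.random(n_steps) * (2.0 * np.pi)
        beta = np.asarray(params.beta_sources[i].ppf(u), dtype=float)
        sx = beta * np.cos(theta)
        sy = beta * np.sin(theta)
        pos = np.zeros((n_steps + 1, 2))
        prev_x = prev_y = 0.0
        for k in range(n_steps):
            if k == 0:
                prev_x, prev_y = sx[0], sy[0]
            else:
                prev_x = prev_x / params.A_cth + sx[k]
                prev_y = prev_y / params.A_cth + sy[k]
            pos[k + 1, 0] = pos[k, 0] + prev_x
            pos[k + 1, 1] = pos[k, 1] + prev_y
        times = np.arange(n_steps + 1) * step_dt
        data[i] = (times, pos)
    return TrajectoryTable(data)


# ---------------------------------------------------------------------------
# localization error


def add_localization_error(
    traj: TrajectoryTable, sigma_err: float, seed: int
) -> TrajectoryTable:
    """Add i.i.d. zero-mean Gaussian noise of s.d. ``sigma_err`` to every coordinate.

    Models the position measurement error of the microscope; adds 4·σ_err² to
    the two-dimensional MSD at every non-zero lag in expectation.
    """
    if sigma_err < 0:
        raise ValueError(f"sigma_err must be >= 0, got {sigma_err}")
    if sigma_err == 0:
        return TrajectoryTable({cid: (t, xy.copy()) for cid, t, xy in traj.items()})
    rng = np.random.default_rng(seed)
    data = {}
    for cid, t, xy in traj.items():
        data[cid] = (t, xy + sigma_err * rng.standard_normal(xy.shape))
    return TrajectoryTable(data)
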