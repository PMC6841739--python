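"""Synthetic cohorts and image stacks emulating the time-lapse experiment.

The emulated study design is a cohort of N = 212 cells observed for
τ = 1292 min at a 34-min sampling interval, with cell-to-cell spread in speed
and persistence and, for the temporal-noise scenarios, within-cell switching
of step magnitude. Canonical single-cell parameters are the PRW fit values
S = 0.125 μm/min, P = 78 min and localization error σ_err = 1.66 μm.

Per-cell speeds and persistences default to log-normal laws (positive
support, right skew matching the broad persistence spread seen across cells);
the relative spreads (σ_log ≈ 0.35–0.4) are stand-ins chosen to give a
clearly heterogeneous but realistic cohort — the per-cell values of the
original experiment are not published.

Image stacks render each cell as a dark, radially symmetric nucleus with a
brighter rim on a mid-brightness background — the contrast polarity the
tracker's darkness and rim-exclusion scores rely on — plus i.i.d. additive
pixel noise, clipped to the [0, 100] brightness range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import estimation as est
from . import simulate as sim
from .imaging import ImageStack
from .trajectories import TrajectoryTable

__all__ = [
    "DistributionSpec",
    "PopulationParams",
    "BlobSpec",
    "gen_population",
    "gen_image_stack",
    "gen_reference_cohort",
    "CANONICAL",
]

# canonical experiment-scale constants used by the reference cohorts
CANONICAL = {
    "S": 0.125,  # μm/min
    "P": 78.0,  # min
    "sigma_err": 1.66,  # μm
    "n_cells": 212,
    "sampling_dt": 34.0,  # min
    "duration": 1292.0,  # min
    "A_th": 2.5,
    "A_cth": 2.4,
    "step_dt": 68.0,  # min, the discretized persistence
}


@dataclass
class DistributionSpec:
    """A positive-support distribution family for per-cell parameters.

    ``lognormal`` takes ``median`` and ``sigma_log`` (s.d. of log values);
    ``gamma`` takes ``shape`` and ``scale``. A ``sigma_log`` (or ``shape``…)
    of zero degenerates to all mass at the median.
    """

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("lognormal", "gamma"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "lognormal":
            if self.params.get("median", 0) <= 0 or self.params.get("sigma_log", -1) < 0:
                raise ValueError("lognormal needs median > 0 and sigma_log >= 0")
        else:
            if self.params.get("shape", 0) <= 0 or self.params.get("scale", 0) <= 0:
                raise ValueError("gamma needs shape > 0 and scale > 0")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.family == "lognormal":
            mu = np.log(self.params["median"])
            return rng.lognormal(mean=mu, sigma=self.params["sigma_log"], size=n)
        return rng.gamma(shape=self.params["shape"], scale=self.params["scale"], size=n)

    def mean(self) -> float:
        if self.family == "lognormal":
            return self.params["median"] * np.exp(self.params["sigma_log"] ** 2 / 2.0)
        return self.params["shape"] * self.params["scale"]


@dataclass
class PopulationParams:
    """Ground-truth per-cell parameters of a generated cohort."""

    n_cells: int
    S_i: np.ndarray  # μm/min
    P_i: np.ndarray  # min, multiples of sampling_dt
    sigma_err: float  # μm
    sampling_dt: float  # min
    duration: float  # min

    def __post_init__(self) -> None:
        self.S_i = np.asarray(self.S_i, dtype=float)
        self.P_i = np.asarray(self.P_i, dtype=float)
        if self.n_cells < 1 or self.S_i.size != self.n_cells or self.P_i.size != self.n_cells:
            raise ValueError("need one (S_i, P_i) pair per cell, n_cells >= 1")
        if np.any(self.S_i <= 0):
            raise ValueError("all S_i must be > 0")
        mult = self.P_i / self.sampling_dt
        if np.any(self.P_i < self.sampling_dt - 1e-9) or np.any(
            np.abs(mult - np.round(mult)) > 1e-9
        ):
            raise ValueError("all P_i must be positive multiples of sampling_dt")
        if self.duration < 2 * self.sampling_dt:
            raise ValueError("duration must span at least two sampling intervals")


def gen_population(
    n_cells: int,
    speed_law: DistributionSpec,
    persistence_law: DistributionSpec,
    sigma_err: float,
    sampling_dt: float,
    duration: float,
    seed: int,
) -> PopulationParams:
    """Draw a cohort of per-cell (S_i, P_i); P_i snapped to the sampling grid."""
    if sigma_err < 0 or sampling_dt <= 0:
        raise ValueError("sigma_err must be >= 0 and sampling_dt > 0")
    rng = np.random.default_rng(seed)
    S_i = speed_law.sample(n_cells, rng)
    P_raw = persistence_law.sample(n_cells, rng)
    P_i = np.array(
        [est.discretize_persistence(max(p, 1e-9), sampling_dt) for p in P_raw]
    )
    return PopulationParams(n_cells, S_i, P_i, sigma_err, sampling_dt, duration)


# ---------------------------------------------------------------------------
# image stacks


@dataclass
class BlobSpec:
    """Appearance of one rendered nucleus."""

    nucleus_radius: float = 25.0  # μm
    nucleus_brightness: float = 5.0  # darkest, at the centre
    rim_brightness: float = 60.0  # at the nucleus edge
    background: float = 30.0
    noise_sd: float = 0.0  # brightness units

    def __post_init__(self) -> None:
        for name in ("nucleus_brightness", "rim_brightness", "background"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must lie in [0, 100]")
        if self.nucleus_radius <= 0 or self.noise_sd < 0:
            raise ValueError("nucleus_radius must be > 0 and noise_sd >= 0")


def gen_image_stack(
    traj: TrajectoryTable,
    height: int,
    width: int,
    blob: BlobSpec | None = None,
    seed: int = 0,
    pixel_size: float = 5.0,
) -> ImageStack:
    """Render a trajectory table into a synthetic image stack.

    One frame per trajectory time point (the frame interval is the table's
    sampling interval); positions are interpreted in μm. Every cell must stay
    at least one nucleus radius inside the image bounds.
    """
    blob = blob or BlobSpec()
    rng = np.random.default_rng(seed)
    dts = {traj.dt(c) for c in traj.cell_ids}
    n_frames = {traj.positions(c)[0].size for c in traj.cell_ids}
    if len(dts) != 1 or len(n_frames) != 1:
        raise ValueError("all cells must share one frame grid to render a stack")
    frame_interval = dts.pop()
    n_frames = n_frames.pop()
    r_px = blob.nucleus_radius / pixel_size
    frames = np.full((n_frames, height, width), blob.background)
    ys, xs = np.mgrid[0:height, 0:width]
    for cid, _, xy in traj.items():
        pos_px = xy / pixel_size
        for k in range(n_frames):
            cx, cy = pos_px[k]
            if not (r_px <= cx <= width - 1 - r_px and r_px <= cy <= height - 1 - r_px):
                raise ValueError(
                    f"cell {cid!r} outside image bounds (margin {blob.nucleus_radius} μm)"
                    f" in frame {k}"
                )
            d2 = (xs - cx) ** 2 + (ys - cy) ** 2
            inside = d2 <= r_px * r_px
            profile = blob.nucleus_brightness + (
                blob.rim_brightness - blob.nucleus_brightness
            ) * (d2 / (r_px * r_px))
            frames[k] = np.where(inside, np.minimum(frames[k], profile), frames[k])
    if blob.noise_sd > 0:
        frames = frames + blob.noise_sd * rng.standard_normal(frames.shape)
    frames = np.clip(frames, 0.0, 100.0)
    return ImageStack(frames, pixel_size=pixel_size, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# reference cohorts for the four heterogeneity scenarios


def _default_speed_law() -> DistributionSpec:
    return DistributionSpec("lognormal", {"median": CANONICAL["S"], "sigma_log": 0.35})


def _default_persistence_law() -> DistributionSpec:
    return DistributionSpec("lognormal", {"median": CANONICAL["P"], "sigma_log": 0.4})


def _two_state_step_magnitudes(
    rng: np.random.Generator,
    n: int,
    mean_square: float,
    fast_slow_ratio: float = 3.0,
    p_fast: float = 0.5,
) -> np.ndarray:
    """Step magnitudes of a cell switching between a slow and a fast state.

    Each draw picks a state, then a Rayleigh magnitude with the state's scale;
    the fast state's Rayleigh scale is ``fast_slow_ratio`` times the slow one.
    ``mean_square`` fixes ⟨β²⟩ so the cohort reproduces the target
    displacement scale. The mixture is strongly non-Gaussian (α₂ ≈ 0.64 at
    ratio 3), emulating within-cell temporal transitions in migration state.
    """
    r2 = fast_slow_ratio**2
    # per-state per-component variances v and r²·v with ⟨β²⟩ = 2v(1-p+p·r²)
    v = mean_square / (2.0 * ((1.0 - p_fast) + p_fast * r2))
    fast = rng.random(n) < p_fast
    scale = np.where(fast, np.sqrt(r2 * v), np.sqrt(v))
    return rng.rayleigh(scale=scale)


def _prw_step_mean_square(S: float, P: float) -> float:
    """⟨(Δr)²⟩ of a PRW over one persistence time (no noise floor)."""
    return 2.0 * S * S * P * P * float(np.exp(-1.0))  # e⁻¹ + 1 − 1 term at t = P


def gen_reference_cohort(
    scenario: str,
    seed: int,
    n_cells: int | None = None,
    duration: float | None = None,
    integration_dt: float = 0.01,
    with_error: bool = True,
) -> tuple[TrajectoryTable, PopulationParams]:
    """Generate a ground-truth cohort under one of the four scenarios.

    ``scenario`` is one of ``homogeneous`` (one (S, P) for all cells),
    ``cellular`` (per-cell log-normal (S_i, P_i)), ``temporal`` (shared
    empirical step sampler on the discretized-persistence grid) or
    ``combined`` (per-cell samplers and step grids estimated from a
    cell-heterogeneous cohort, the full estimation chain of the experiment).
    Localization error is applied unless ``with_error=False``.
    """
    n = n_cells or CANONICAL["n_cells"]
    dur = duration or CANONICAL["duration"]
    dt = CANONICAL["sampling_dt"]
    sigma = CANONICAL["sigma_err"] if with_error else 0.0
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    if scenario == "homogeneous":
        pop = PopulationParams(
            n, np.full(n, CANONICAL["S"]),
            np.full(n, est.discretize_persistence(CANONICAL["P"], dt)),
            sigma, dt, dur,
        )
        params = sim.HOParams(
            CANONICAL["S"], CANONICAL["P"], sigma, integration_dt, dt
        )
        traj = sim.simulate_ho(params, n, dur, seeds[0])
    elif scenario == "cellular":
        pop_draw = gen_population(
            n, _default_speed_law(), _default_persistence_law(), sigma, dt, dur,
            seeds[0],
        )
        pop = pop_draw
        params = sim.CHParams(
            pop.S_i, pop.P_i, sigma, integration_dt, dt
        )
        traj = sim.simulate_ch(params, dur, seeds[1])
    elif scenario == "temporal":
        rng = np.random.default_rng(seeds[0])
        m2 = _prw_step_mean_square(CANONICAL["S"], CANONICAL["step_dt"])
        sampler = est.DisplacementSampler(
            _two_state_step_magnitudes(rng, 4000, m2), CANONICAL["step_dt"],
            seed=seeds[1],
        )
        params = sim.THParams(
            CANONICAL["A_th"], sampler, n, dur, CANONICAL["step_dt"]
        )
        traj = sim.simulate_th(params, seeds[2])
        pop = PopulationParams(
            n, np.full(n, CANONICAL["S"]), np.full(n, CANONICAL["step_dt"]),
            sigma, dt, dur,
        )
    elif scenario == "combined":
        base_pop = gen_population(
            n, _default_speed_law(), _default_persistence_law(), 0.0, dt, dur,
            seeds[0],
        )
        # cap P_i at half the observation window so every cell takes >= 2 steps
        p_cap = est.discretize_persistence(dur / 2.0, dt)
        base_pop.P_i = np.minimum(base_pop.P_i, p_cap)
        rng = np.random.default_rng(seeds[1])
        samplers = [
            est.DisplacementSampler(
                _two_state_step_magnitudes(
                    rng, 1000, _prw_step_mean_square(S_c, P_c)
                ),
                P_c, seed=seeds[2] + k,
            )
            for k, (S_c, P_c) in enumerate(zip(base_pop.S_i, base_pop.P_i))
        ]
        params = sim.CTHParams(CANONICAL["A_cth"], base_pop.P_i, samplers, dur)
        traj = sim.simulate_cth(params, seeds[3])
        pop = PopulationParams(
            n, base_pop.S_i, base_pop.P_i, sigma, dt, dur
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    if sigma > 0:
        traj = sim.add_localization_error(traj, sigma, seeds[3] + 1)
    return traj, pop
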