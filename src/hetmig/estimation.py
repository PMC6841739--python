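"""Parameter estimation for the migration models.

* :func:`fit_prw_msd` — nonlinear least squares of the analytic PRW ensemble
  MSD (with localization-error offset)

      ⟨(Δr)²(t)⟩ = 2S²P²(e^{−t/P} + t/P − 1) + 4σ_err²

  over (S, P, σ_err) with positivity constraints and multi-start
  initialization. Residuals are weighted by the curve's per-lag standard
  errors when available, which is what makes the small σ_err offset
  identifiable from the precisely determined short lags.
* :func:`estimate_percell` — per-cell persistence P_i from the first downward
  1/e crossing of the cell's normalized velocity autocorrelation (linear
  interpolation between bracketing lags, then snapped to the sampling grid)
  and per-cell speed S_i as the time-mean speed.
* :func:`discretize_persistence` — nearest positive multiple of the sampling
  interval. The estimators feeding the step-based models require step lengths
  commensurate with the sampling grid; the nearest-multiple rule maps a
  78-min persistence on a 34-min grid to 68 min.
* :class:`DisplacementSampler` — empirical step-length distribution at a
  reference lag, invertible for inverse-transform sampling of β.
* :func:`calibrate_memory` — scalar search for the memory parameter A of the
  step-based walks by matching the replicate-averaged simulated ensemble MSD
  to a reference MSD curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, minimize_scalar

from . import simulate as sim
from . import statistics as stats
from .trajectories import TrajectoryTable

__all__ = [
    "PRWFit",
    "eval_prw_msd",
    "fit_prw_msd",
    "PerCellEstimates",
    "estimate_percell",
    "discretize_persistence",
    "DisplacementSampler",
    "build_displacement_sampler",
    "MemoryCalibration",
    "calibrate_memory",
]

E_INV = float(np.exp(-1.0))


# ---------------------------------------------------------------------------
# analytic PRW MSD and its fit


def eval_prw_msd(S: float, P: float, sigma_err: float, t) -> np.ndarray:
    """2S²P²(e^{−t/P} + t/P − 1) + 4σ_err², the 2-D PRW MSD with noise floor."""
    if P <= 0:
        raise ValueError(f"P must be > 0, got {P}")
    t = np.asarray(t, dtype=float)
    x = t / P
    return 2.0 * S * S * P * P * (np.exp(-x) + x - 1.0) + 4.0 * sigma_err**2


@dataclass
class PRWFit:
    """Result of the PRW MSD least-squares fit."""

    S: float  # μm/min
    P: float  # min
    sigma_err: float  # μm
    rss: float  # unweighted residual sum of squares, μm⁴
    lags: np.ndarray  # lags used in the fit, min
    bse: np.ndarray = field(default=None)  # standard errors of (S, P, sigma_err)
    cost: float = np.nan  # weighted least-squares cost

    @property
    def params(self) -> np.ndarray:
        return np.array([self.S, self.P, self.sigma_err])


def _fit_starts(t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    t_max = t[-1]
    i0 = max(0, t.size // 2)
    denom = t[-1] - t[i0] if t[-1] > t[i0] else t[-1]
    slope = max((y[-1] - y[i0]) / denom, 1e-12)
    sigma0 = np.sqrt(max(y[0], 1e-12)) / 4.0
    starts = []
    for P0 in (t[0], t_max / 8.0, t_max / 3.0):
        S0 = np.sqrt(slope / (2.0 * P0))
        starts.append(np.array([S0, P0, sigma0]))
        starts.append(np.array([3.0 * S0, P0, 0.3 * sigma0 + 1e-6]))
        starts.append(np.array([0.3 * S0, P0, 3.0 * sigma0]))
    return starts


def fit_prw_msd(
    curve: stats.MSDCurve,
    exclude_lags: Sequence[float] = (),
    weighted: bool = True,
) -> PRWFit:
    """Fit (S, P, σ_err) to an ensemble MSD curve.

    ``exclude_lags`` removes listed lags (e.g. the first sampling interval)
    from the fit; lag 0 is always excluded since the measured MSD there is
    identically zero while the model carries the 4σ_err² noise floor.
    """
    excl = set(round(float(l), 6) for l in exclude_lags)
    mask = np.array(
        [lag > 0 and round(float(lag), 6) not in excl for lag in curve.lags]
    )
    t = curve.lags[mask]
    y = curve.values[mask]
    if t.size < 4:
        raise ValueError(f"need at least 4 lags after exclusion, have {t.size}")
    if weighted and curve.sem is not None and np.all(curve.sem[mask] > 0):
        w = 1.0 / curve.sem[mask]
        w = w / w.mean()
    else:
        w = np.ones_like(y)

    def resid(theta):
        S, P, sig = theta
        return (eval_prw_msd(S, P, sig, t) - y) * w

    bounds = ([0.0, 1e-6, 0.0], [np.inf, np.inf, np.inf])
    best = None
    for x0 in _fit_starts(t, y):
        try:
            res = least_squares(
                resid, x0, bounds=bounds, ftol=1e-15, xtol=1e-15, gtol=1e-15,
                max_nfev=20000,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("PRW MSD fit failed to converge from every start")
    S, P, sig = best.x
    raw = eval_prw_msd(S, P, sig, t) - y
    rss = float(np.sum(raw**2))
    bse = np.full(3, np.nan)
    dof = t.size - 3
    if dof > 0:
        try:
            JTJ = best.jac.T @ best.jac
            cov = np.linalg.inv(JTJ) * (2.0 * best.cost / dof)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            pass
    return PRWFit(float(S), float(P), float(sig), rss, t.copy(), bse, float(best.cost))


# ---------------------------------------------------------------------------
# per-cell estimation


def discretize_persistence(P_continuous: float, sampling_dt: float) -> float:
    """Nearest positive multiple of ``sampling_dt`` (half-way rounds up)."""
    if P_continuous <= 0:
        raise ValueError(f"P_continuous must be > 0, got {P_continuous}")
    if sampling_dt <= 0:
        raise ValueError(f"sampling_dt must be > 0, got {sampling_dt}")
    k = int(np.floor(P_continuous / sampling_dt + 0.5))
    return float(max(1, k) * sampling_dt)


@dataclass
class PerCellEstimates:
    """Per-cell (S_i, P_i) estimates from finite-difference velocities."""

    cell_ids: list
    S_i: np.ndarray  # μm/min, time-mean speed
    P_cont: np.ndarray  # min, 1/e crossing of the VACF (linear interpolation)
    P_disc: np.ndarray  # min, snapped to the sampling grid
    flagged: np.ndarray  # True where the VACF never crossed 1/e
    sampling_dt: float

    def to_ch_params(
        self, sigma_err: float = 0.0, integration_dt: float = 0.01, discrete: bool = False
    ) -> sim.CHParams:
        P = self.P_disc if discrete else self.P_cont
        return sim.CHParams(
            S_i=self.S_i, P_i=P, sigma_err=sigma_err,
            integration_dt=integration_dt, sampling_dt=self.sampling_dt,
        )


def _first_crossing(lags: np.ndarray, vals: np.ndarray, level: float) -> float | None:
    """First downward crossing of ``level``, located by linear interpolation."""
    for k in range(1, vals.size):
        if vals[k - 1] >= level > vals[k]:
            frac = (vals[k - 1] - level) / (vals[k - 1] - vals[k])
            return float(lags[k - 1] + frac * (lags[k] - lags[k - 1]))
    return None


def estimate_percell(traj: TrajectoryTable, dt: float | None = None) -> PerCellEstimates:
    """Estimate (S_i, P_i) for every cell.

    P_i is the first downward 1/e crossing of the cell's normalized VACF;
    cells whose VACF never crosses 1/e within the observed lags are flagged
    and assigned the maximum observed lag. S_i is the time-mean speed.
    """
    vel = stats.velocities(traj, dt=dt)
    cell_ids, S_i, P_cont, P_disc, flagged = [], [], [], [], []
    sampling_dt = None
    for cid, (t, v) in vel.items():
        if v.shape[0] < 2:
            raise ValueError(f"cell {cid!r}: need at least 3 frames")
        step = float(t[1] - t[0])
        sampling_dt = step if sampling_dt is None else sampling_dt
        lags, vals = np.arange(v.shape[0]) * step, stats.vacf_from_velocities(v)
        crossing = _first_crossing(lags, vals, E_INV)
        if crossing is None:
            flagged.append(True)
            crossing = float(lags[-1])
        else:
            flagged.append(False)
        cell_ids.append(cid)
        S_i.append(float(np.mean(np.hypot(v[:, 0], v[:, 1]))))
        P_cont.append(crossing)
        P_disc.append(discretize_persistence(crossing, step))
    return PerCellEstimates(
        cell_ids, np.asarray(S_i), np.asarray(P_cont), np.asarray(P_disc),
        np.asarray(flagged), float(sampling_dt),
    )


# ---------------------------------------------------------------------------
# empirical displacement sampler


@dataclass
class DisplacementSampler:
    """Empirical step-length distribution, invertible for sampling β.

    The quantile function interpolates linearly between order statistics, so
    draws always lie within [min, max] of the source magnitudes.
    """

    magnitudes: np.ndarray  # μm, sorted ascending
    lag: float  # min, the reference lag the magnitudes were measured at
    seed: int = 0

    def __post_init__(self) -> None:
        mags = np.sort(np.asarray(self.magnitudes, dtype=float))
        if mags.size < 2:
            raise ValueError("need at least 2 source displacement magnitudes")
        if np.any(mags < 0):
            raise ValueError("displacement magnitudes must be >= 0")
        self.magnitudes = mags
        self._grid = np.linspace(0.0, 1.0, mags.size)
        self._rng = np.random.default_rng(self.seed)

    def ppf(self, u) -> np.ndarray:
        """Inverse CDF: maps uniforms in [0, 1] to displacement magnitudes."""
        return np.interp(np.asarray(u, dtype=float), self._grid, self.magnitudes)

    def cdf(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.magnitudes, self._grid)

    def draw(self, n: int) -> np.ndarray:
        """Draw ``n`` magnitudes using the sampler's own seeded stream."""
        return self.ppf(self._rng.random(n))


def build_displacement_sampler(
    traj: TrajectoryTable, lag: float, scope="ensemble", seed: int = 0
) -> DisplacementSampler:
    """Sampler over displacement magnitudes at ``lag`` (ensemble or one cell)."""
    mags = stats.displacements(traj, lag, scope=scope)
    if mags.size < 2:
        raise ValueError(f"scope {scope!r}: fewer than 2 displacements at lag {lag}")
    return DisplacementSampler(mags, lag, seed)


# ---------------------------------------------------------------------------
# memory-parameter calibration


@dataclass
class MemoryCalibration:
    A: float
    objective: float
    lags: np.ndarray
    n_replicates: int
    model: str


def _ensemble_msd_mean(tables, lags) -> np.ndarray:
    vals = [stats.msd(tab, lags).values for tab in tables]
    return np.mean(vals, axis=0)


def calibrate_memory(
    reference: stats.MSDCurve,
    beta_source,
    step_dt,
    model: str = "th",
    *,
    n_cells: int | None = None,
    duration: float,
    n_replicates: int = 50,
    seed: int = 0,
    bounds: tuple[float, float] = (1.01, 20.0),
    xatol: float = 0.005,
    sigma_err: float = 0.0,
) -> MemoryCalibration:
    """Calibrate the memory parameter A by replicate-averaged MSD matching.

    ``beta_source``/``step_dt`` are a single sampler and step length for the
    temporally heterogeneous model (``model="th"``, needs ``n_cells``), or a
    sequence of per-cell samplers and per-cell step lengths for the combined
    model (``model="cth"``). The objective is the mean squared deviation of
    log MSD between the simulated replicate-average and the reference at the
    reference lags reachable by the step grid; the log scale balances the
    short, well-determined lags against the long, noisy ones. Inner replicate
    seeds are fixed so the objective is a smooth deterministic function of A.

    If the reference MSD was measured with localization error, pass its
    ``sigma_err``: the expected noise floor 4σ_err² is added to the simulated
    MSD instead of injecting noise into every replicate.
    """
    if model not in ("th", "cth"):
        raise ValueError(f"unknown model {model!r}")
    rep_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                 np.random.SeedSequence(seed).spawn(n_replicates)]

    if model == "th":
        if n_cells is None:
            raise ValueError("n_cells is required for the th model")
        step_arr = np.array([float(step_dt)])
    else:
        step_arr = np.asarray(step_dt, dtype=float)
        n_cells = step_arr.size

    # reference lags reachable by at least one cell's step grid
    usable = []
    for lag in reference.lags:
        if lag <= 0 or lag > duration:
            continue
        k = lag / step_arr
        if np.any(np.abs(k - np.round(k)) < 1e-8):
            usable.append(float(lag))
    usable = np.asarray(usable)
    if usable.size < 2:
        raise ValueError("fewer than 2 reference lags reachable by the step grid")
    sel = np.isin(reference.lags, usable)
    ref_vals = reference.values[sel]
    if np.any(ref_vals <= 0):
        raise ValueError("reference MSD must be positive at the usable lags")
    log_ref = np.log(ref_vals)
    # weight lags by how many cells informed them: per-cell step grids leave
    # some lags with few contributing cells, whose MSD is much noisier
    if reference.n_cells is not None:
        weights = reference.n_cells[sel].astype(float)
    else:
        weights = np.ones_like(ref_vals)
    weights = weights / weights.sum()

    def simulate_once(A: float, rep_seed: int) -> TrajectoryTable:
        if model == "th":
            params = sim.THParams(
                A_th=A, beta_source=beta_source, n_cells=n_cells,
                duration=duration, step_dt=float(step_dt),
            )
            return sim.simulate_th(params, rep_seed)
        params = sim.CTHParams(
            A_cth=A, P_i=step_arr, beta_sources=beta_source, duration=duration
        )
        return sim.simulate_cth(params, rep_seed)

    def objective(A: float) -> float:
        tables = [simulate_once(A, rs) for rs in rep_seeds]
        mean_msd = _ensemble_msd_mean(tables, usable) + 4.0 * sigma_err**2
        if np.any(mean_msd <= 0) or not np.all(np.isfinite(mean_msd)):
            raise FloatingPointError("non-finite or non-positive simulated MSD")
        return float(np.sum(weights * (np.log(mean_msd) - log_ref) ** 2))

    res = minimize_scalar(
        objective, bounds=bounds, method="bounded", options={"xatol": xatol}
    )
    return MemoryCalibration(
        float(res.x), float(res.fun), usable, n_replicates, model
    )
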