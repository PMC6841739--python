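"""Descriptive statistics of 2-D migration trajectories.

All time-lagged quantities are averaged over **all overlapping time origins**
within each cell, then (where applicable) over cells:

* ``msd`` — mean-square displacement ⟨(Δr)²(t)⟩, time-origin and ensemble
  averaged, with per-lag standard errors of the mean over cells.
* ``self_correlation_single`` / ``self_correlation_ensemble`` — the radial
  self part of the van Hove function, g_i(r, t) for one cell and its
  population average G(r, t) = (1/N) Σ g_i(r, t). Densities are reported per
  unit area (μm⁻²) so that 2πr·g(r, t) is the probability density of moving a
  distance r in time t; the histogram normalization is exact because the
  annulus area π(r_hi² − r_lo²) equals 2π·r_mid·Δr.
* ``rescale_correlation`` — g_i curves mapped to (r/r*, πr*²·g_i) with r* the
  cell's RMS displacement at the lag; Gaussian cells collapse onto exp(−u²).
* ``vacf`` — normalized velocity autocorrelation ⟨v(t)·v(0)⟩/⟨v²(0)⟩.
* ``acceleration_stats`` — finite-difference acceleration decomposed along
  and orthogonal to the instantaneous velocity, conditionally averaged on the
  speed.

Cells whose sampling grid is incommensurate with a requested lag (the
step-based models give each cell its own grid) are excluded from that lag
rather than interpolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectories import TrajectoryTable

__all__ = [
    "MSDCurve",
    "CorrelationCurve",
    "RescaledCurve",
    "AccelerationStats",
    "velocities",
    "msd",
    "displacements",
    "per_cell_rms_displacement",
    "self_correlation_single",
    "self_correlation_ensemble",
    "gaussian_reference",
    "rescale_correlation",
    "default_bin_edges",
    "vacf",
    "vacf_from_velocities",
    "acceleration_stats",
]

_LAG_RTOL = 1e-6


def _lag_steps(lag: float, dt: float) -> int | None:
    """Lag expressed in grid steps, or None if incommensurate."""
    k = lag / dt
    k_round = int(round(k))
    if k_round < 1 or abs(k - k_round) > _LAG_RTOL * max(1.0, k):
        return None
    return k_round


# ---------------------------------------------------------------------------
# velocities


def velocities(traj: TrajectoryTable, dt: float | None = None) -> dict:
    """Finite-difference velocities v(t) = (r(t+Δt) − r(t))/Δt per cell.

    ``dt`` defaults to each cell's own sampling interval and must be a grid
    multiple. Returns ``{cell_id: (t, v)}`` with ``v`` of shape (n − m, 2).
    """
    out = {}
    for cid, t, xy in traj.items():
        cell_dt = float(t[1] - t[0])
        use_dt = cell_dt if dt is None else dt
        m = _lag_steps(use_dt, cell_dt)
        if m is None:
            raise ValueError(
                f"cell {cid!r}: dt={use_dt} is not a multiple of the grid ({cell_dt})"
            )
        v = (xy[m:] - xy[:-m]) / use_dt
        out[cid] = (t[:-m], v)
    return out


# ---------------------------------------------------------------------------
# mean-square displacement


@dataclass
class MSDCurve:
    """Ensemble MSD: per-lag value, SEM over cells and contributing-cell count."""

    lags: np.ndarray  # min
    values: np.ndarray  # μm²
    sem: np.ndarray  # μm²
    n_cells: np.ndarray  # cells contributing per lag

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_min": self.lags, "msd_um2": self.values, "sem_um2": self.sem,
             "n_cells": self.n_cells}
        )


def _cell_msd_at(xy: np.ndarray, k: int) -> float:
    d = xy[k:] - xy[:-k]
    return float(np.mean(np.einsum("ij,ij->i", d, d)))


def _common_grid_positions(traj: TrajectoryTable):
    """Stacked (n_cells, n_frames, 2) positions if all cells share one grid."""
    ref_t = None
    arrays = []
    for _, t, xy in traj.items():
        if ref_t is None:
            ref_t = t
        elif t.size != ref_t.size or not np.allclose(t, ref_t, atol=1e-9):
            return None
        arrays.append(xy)
    return ref_t, np.stack(arrays)


def msd(traj: TrajectoryTable, lags) -> MSDCurve:
    """Time-origin- then ensemble-averaged MSD at the requested lags (min)."""
    lags = np.atleast_1d(np.asarray(lags, dtype=float))
    common = _common_grid_positions(traj)
    if common is not None:
        return _msd_common(common[0], common[1], lags)
    max_dur = max(traj.duration(c) for c in traj.cell_ids)
    values, sems, counts = [], [], []
    for lag in lags:
        if lag < 0:
            raise ValueError(f"negative lag {lag}")
        if lag == 0:
            values.append(0.0)
            sems.append(0.0)
            counts.append(traj.n_cells)
            continue
        if lag > max_dur + 1e-9:
            raise ValueError(f"lag {lag} min exceeds every cell's duration")
        per_cell = []
        for cid, t, xy in traj.items():
            k = _lag_steps(lag, float(t[1] - t[0]))
            if k is None or k >= t.size:
                continue
            per_cell.append(_cell_msd_at(xy, k))
        if not per_cell:
            raise ValueError(f"no cell has a grid commensurate with lag {lag} min")
        arr = np.asarray(per_cell)
        values.append(float(arr.mean()))
        sems.append(float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0)
        counts.append(arr.size)
    return MSDCurve(lags, np.asarray(values), np.asarray(sems), np.asarray(counts))


def _msd_common(t: np.ndarray, pos: np.ndarray, lags: np.ndarray) -> MSDCurve:
    """Vectorized MSD for cohorts whose cells share one time grid."""
    dt = float(t[1] - t[0])
    duration = float(t[-1] - t[0])
    n_cells, n_frames, _ = pos.shape
    values, sems, counts = [], [], []
    for lag in lags:
        if lag < 0:
            raise ValueError(f"negative lag {lag}")
        if lag == 0:
            values.append(0.0)
            sems.append(0.0)
            counts.append(n_cells)
            continue
        if lag > duration + 1e-9:
            raise ValueError(f"lag {lag} min exceeds every cell's duration")
        k = _lag_steps(lag, dt)
        if k is None or k >= n_frames:
            raise ValueError(f"no cell has a grid commensurate with lag {lag} min")
        d = pos[:, k:, :] - pos[:, :-k, :]
        per_cell = np.mean(np.sum(d * d, axis=2), axis=1)
        values.append(float(per_cell.mean()))
        sems.append(
            float(per_cell.std(ddof=1) / np.sqrt(n_cells)) if n_cells > 1 else 0.0
        )
        counts.append(n_cells)
    return MSDCurve(lags, np.asarray(values), np.asarray(sems), np.asarray(counts))


# ---------------------------------------------------------------------------
# displacement magnitudes and van Hove functions


def displacements(traj: TrajectoryTable, lag: float, scope="ensemble") -> np.ndarray:
    """Displacement magnitudes |r(t+lag) − r(t)| over all origins.

    ``scope`` is ``"ensemble"`` (pool commensurate cells) or a single cell id.
    """
    cells = traj.cell_ids if scope == "ensemble" else [scope]
    mags = []
    for cid in cells:
        t, xy = traj.positions(cid)
        k = _lag_steps(lag, float(t[1] - t[0]))
        if k is None or k >= t.size:
            if scope != "ensemble":
                raise ValueError(f"cell {cid!r}: lag {lag} not on the cell's grid")
            continue
        d = xy[k:] - xy[:-k]
        mags.append(np.hypot(d[:, 0], d[:, 1]))
    if not mags:
        raise ValueError(f"no displacements available at lag {lag}")
    return np.concatenate(mags)


def per_cell_rms_displacement(traj: TrajectoryTable, lag: float) -> dict:
    """r* per cell: the root of the cell's time-averaged MSD at ``lag``."""
    out = {}
    for cid, t, xy in traj.items():
        k = _lag_steps(lag, float(t[1] - t[0]))
        if k is None or k >= t.size:
            continue
        out[cid] = float(np.sqrt(_cell_msd_at(xy, k)))
    return out


@dataclass
class CorrelationCurve:
    """Radial density estimate of g_i(r, t) or G(r, t) at one lag."""

    lag: float  # min
    bin_edges: np.ndarray  # μm
    densities: np.ndarray  # μm⁻²
    cell_id: object = "ensemble"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def normalization(self) -> float:
        """Σ density · 2π·r_mid·Δr, equal to 1 for a proper histogram."""
        widths = np.diff(self.bin_edges)
        return float(np.sum(self.densities * 2.0 * np.pi * self.bin_centers * widths))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lag_min": self.lag,
                "bin_lo_um": self.bin_edges[:-1],
                "bin_hi_um": self.bin_edges[1:],
                "density_per_um2": self.densities,
                "cell_id": str(self.cell_id),
            }
        )


def default_bin_edges(max_r: float, width: float = 2.5) -> np.ndarray:
    """Radial bin edges [0, width, 2·width, …] covering ``max_r``."""
    n = max(1, int(np.ceil((max_r + 1e-12) / width)))
    return np.arange(n + 1) * width


def _radial_density(mags: np.ndarray, bin_edges: np.ndarray) -> np.ndarray:
    bin_edges = np.asarray(bin_edges, dtype=float)
    if mags.max(initial=0.0) > bin_edges[-1]:
        raise ValueError(
            f"displacement {mags.max():.3f} μm exceeds the last bin edge "
            f"{bin_edges[-1]:.3f} μm; enlarge the binning range"
        )
    counts, _ = np.histogram(mags, bins=bin_edges)
    prob = counts / mags.size
    areas = np.pi * (bin_edges[1:] ** 2 - bin_edges[:-1] ** 2)
    return prob / areas


def self_correlation_single(
    traj: TrajectoryTable, cell_id, lag: float, bin_edges
) -> CorrelationCurve:
    """g_i(r, t): radial displacement density of one cell at one lag."""
    mags = displacements(traj, lag, scope=cell_id)
    dens = _radial_density(mags, np.asarray(bin_edges, dtype=float))
    return CorrelationCurve(lag, np.asarray(bin_edges, dtype=float), dens, cell_id)


def self_correlation_ensemble(
    traj: TrajectoryTable, lag: float, bin_edges
) -> CorrelationCurve:
    """G(r, t): unweighted mean of the per-cell g_i(r, t) over all cells."""
    if traj.n_cells == 0:
        raise ValueError("trajectory table has no cells")
    curves = []
    for cid in traj.cell_ids:
        try:
            curves.append(self_correlation_single(traj, cid, lag, bin_edges))
        except ValueError as exc:
            if "not on the cell's grid" in str(exc):
                continue
            raise
    if not curves:
        raise ValueError(f"no cell has a grid commensurate with lag {lag} min")
    dens = np.mean([c.densities for c in curves], axis=0)
    return CorrelationCurve(lag, np.asarray(bin_edges, dtype=float), dens, "ensemble")


def gaussian_reference(lag: float, msd_value: float, bin_edges) -> CorrelationCurve:
    """The 2-D Gaussian guideline G(r) = exp(−r²/⟨Δr²⟩)/(π⟨Δr²⟩) at bin centres."""
    if msd_value <= 0:
        raise ValueError(f"msd_value must be > 0, got {msd_value}")
    edges = np.asarray(bin_edges, dtype=float)
    r = 0.5 * (edges[:-1] + edges[1:])
    dens = np.exp(-(r**2) / msd_value) / (np.pi * msd_value)
    return CorrelationCurve(lag, edges, dens, "gaussian")


@dataclass
class RescaledCurve:
    """g_i curves rescaled to (r/r*, πr*²·g_i), binned on the x axis."""

    x_centers: np.ndarray  # r/r*, dimensionless
    mean: np.ndarray  # πr*²·g_i
    sem: np.ndarray
    counts: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_center": self.x_centers, "mean": self.mean, "sem": self.sem,
             "count": self.counts}
        )


def rescale_correlation(
    curves, r_stars, x_bin_width: float = 0.25
) -> RescaledCurve:
    """Pool rescaled per-cell curves and bin them on r/r*.

    ``curves`` are per-cell :class:`CorrelationCurve` objects; ``r_stars`` maps
    each curve's ``cell_id`` to the cell's RMS displacement at the same lag.
    Cells with r* = 0 are excluded with a warning.
    """
    xs, ys = [], []
    for curve in curves:
        r_star = r_stars[curve.cell_id]
        if r_star <= 0:
            warnings.warn(f"cell {curve.cell_id!r} excluded: r* = 0", stacklevel=2)
            continue
        xs.append(curve.bin_centers / r_star)
        ys.append(np.pi * r_star**2 * curve.densities)
    if not xs:
        raise ValueError("no cell with positive r*")
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n_bins = int(np.ceil(x.max() / x_bin_width)) or 1
    idx = np.minimum((x / x_bin_width).astype(int), n_bins - 1)
    centers = (np.arange(n_bins) + 0.5) * x_bin_width
    mean = np.full(n_bins, np.nan)
    sem = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = y[idx == b]
        counts[b] = sel.size
        if sel.size:
            mean[b] = sel.mean()
            sem[b] = sel.std(ddof=1) / np.sqrt(sel.size) if sel.size > 1 else 0.0
    keep = counts > 0
    return RescaledCurve(centers[keep], mean[keep], sem[keep], counts[keep])


# ---------------------------------------------------------------------------
# velocity autocorrelation


def vacf_from_velocities(v: np.ndarray) -> np.ndarray:
    """Normalized VACF of one velocity series (n, 2) by time-origin averaging."""
    v = np.asarray(v, dtype=float)
    n = v.shape[0]
    if n < 2:
        raise ValueError("need at least two velocity samples")
    num = np.empty(n)
    for k in range(n):
        num[k] = np.mean(np.einsum("ij,ij->i", v[: n - k], v[k:]))
    if num[0] == 0:
        raise ValueError("zero-variance velocity series")
    return num / num[0]


def vacf(traj: TrajectoryTable, cell_id, dt: float | None = None):
    """Normalized VACF of one cell from finite-difference velocities.

    Returns ``(lags, values)`` with value 1 at lag 0.
    """
    t, v = velocities(traj, dt=dt)[cell_id]
    if v.shape[0] < 2:
        raise ValueError(f"cell {cell_id!r}: need at least 3 frames")
    vals = vacf_from_velocities(v)
    step = float(t[1] - t[0]) if t.size > 1 else 0.0
    return np.arange(vals.size) * step, vals


# ---------------------------------------------------------------------------
# acceleration decomposition


@dataclass
class AccelerationStats:
    """Speed-conditioned acceleration components a_p (along v) and a_np (orthogonal)."""

    speed_centers: np.ndarray  # μm/min
    mean_ap: np.ndarray  # μm/min²
    mean_anp: np.ndarray
    mad_ap: np.ndarray  # mean |a_p − ⟨a_p⟩_v|
    mad_anp: np.ndarray
    counts: np.ndarray

    def filtered(self, min_count: int = 10) -> "AccelerationStats":
        keep = self.counts >= min_count
        return AccelerationStats(
            self.speed_centers[keep], self.mean_ap[keep], self.mean_anp[keep],
            self.mad_ap[keep], self.mad_anp[keep], self.counts[keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "speed_center_um_min": self.speed_centers,
                "mean_ap": self.mean_ap,
                "mean_anp": self.mean_anp,
                "mad_ap": self.mad_ap,
                "mad_anp": self.mad_anp,
                "count": self.counts,
            }
        )


def acceleration_stats(
    traj: TrajectoryTable,
    dt: float | None = None,
    speed_bin_width: float = 0.05,
) -> AccelerationStats:
    """Conditional acceleration statistics pooled over cells.

    a(t) = (v(t+dt) − v(t))/dt is decomposed into a_p = a·v̂ and the signed
    orthogonal component a_np; samples with zero speed are skipped (the
    projection is undefined there). Speed bins have width ``speed_bin_width``
    starting at 0; bins below 10 samples should be filtered by the caller via
    :meth:`AccelerationStats.filtered`.
    """
    speeds, aps, anps = [], [], []
    for cid, (t, v) in velocities(traj, dt=dt).items():
        if v.shape[0] < 2:
            raise ValueError(f"cell {cid!r}: need at least 3 frames")
        step = float(t[1] - t[0])
        a = (v[1:] - v[:-1]) / step
        v0 = v[:-1]
        speed = np.hypot(v0[:, 0], v0[:, 1])
        ok = speed > 0
        vhat = v0[ok] / speed[ok, None]
        perp = np.stack([-vhat[:, 1], vhat[:, 0]], axis=1)
        speeds.append(speed[ok])
        aps.append(np.einsum("ij,ij->i", a[ok], vhat))
        anps.append(np.einsum("ij,ij->i", a[ok], perp))
    speed = np.concatenate(speeds)
    ap = np.concatenate(aps)
    anp = np.concatenate(anps)
    n_bins = int(np.ceil(speed.max() / speed_bin_width)) or 1
    idx = np.minimum((speed / speed_bin_width).astype(int), n_bins - 1)
    centers = (np.arange(n_bins) + 0.5) * speed_bin_width
    mean_ap = np.full(n_bins, np.nan)
    mean_anp = np.full(n_bins, np.nan)
    mad_ap = np.full(n_bins, np.nan)
    mad_anp = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            mean_ap[b] = ap[sel].mean()
            mean_anp[b] = anp[sel].mean()
            mad_ap[b] = np.abs(ap[sel] - mean_ap[b]).mean()
            mad_anp[b] = np.abs(anp[sel] - mean_anp[b]).mean()
    keep = counts > 0
    return AccelerationStats(
        centers[keep], mean_ap[keep], mean_anp[keep], mad_ap[keep], mad_anp[keep],
        counts[keep],
    )
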