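"""Model/Results interface over the four migration models.

Each model class is built from an observed :class:`TrajectoryTable` (the data
to explain); ``fit()`` estimates the model's parameters from the data and
returns a Results object carrying the estimates, their uncertainties where
available, and a ``summary()`` table. ``Results.simulate(seed)`` generates a
synthetic cohort of the fitted model at the observed design (same number of
cells, duration and sampling), with localization error applied, so fitted
models can be compared against the data they were fitted to.

The four models:

``HomogeneousModel``        one (S, P) for every cell (the classic PRW),
                            fitted by least squares on the ensemble MSD.
``CellHeterogeneousModel``  per-cell (S_i, P_i) from each cell's mean speed
                            and VACF 1/e decay time.
``TemporalModel``           shared empirical step-magnitude sampler on the
                            discretized-persistence grid, memory parameter
                            A calibrated on the ensemble MSD.
``CombinedModel``           per-cell samplers and step grids plus the
                            calibrated memory parameter (cellular *and*
                            temporal heterogeneity).

The short keys ``ho``/``ch``/``th``/``cth`` name the models throughout
reports and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import estimation as est
from . import simulate as sim
from . import statistics as stats
from .trajectories import TrajectoryTable, read_trajectories

__all__ = [
    "HomogeneousModel",
    "CellHeterogeneousModel",
    "TemporalModel",
    "CombinedModel",
    "MODEL_CLASSES",
]


def _float_gcd(values, atol: float = 1e-6) -> float:
    import math

    ints = [int(round(v / atol)) for v in values]
    g = ints[0]
    for v in ints[1:]:
        g = math.gcd(g, v)
    return g * atol


class _BaseModel:
    """Shared plumbing: data access and the observed ensemble MSD.

    Cohorts from the step-based models carry one grid per cell; the base
    sampling interval is then the greatest common divisor of the per-cell
    intervals, and a lag contributes only the cells whose grid it is
    commensurate with.
    """

    name = "base"

    def __init__(self, traj: TrajectoryTable):
        self.traj = traj

    @classmethod
    def from_csv(cls, path):
        return cls(read_trajectories(path))

    def base_dt(self) -> float:
        return _float_gcd([self.traj.dt(c) for c in self.traj.cell_ids])

    def max_duration(self) -> float:
        return max(self.traj.duration(c) for c in self.traj.cell_ids)

    def observed_lags(self) -> np.ndarray:
        base = self.base_dt()
        durations = {c: self.traj.duration(c) for c in self.traj.cell_ids}
        dts = {c: self.traj.dt(c) for c in self.traj.cell_ids}
        lags = []
        for k in range(1, int(round(self.max_duration() / base)) + 1):
            lag = k * base
            for c in self.traj.cell_ids:
                m = lag / dts[c]
                if abs(m - round(m)) < 1e-9 and lag <= durations[c] + 1e-9:
                    lags.append(lag)
                    break
        return np.asarray(lags)

    def observed_msd(self, lags=None) -> stats.MSDCurve:
        return stats.msd(self.traj, self.observed_lags() if lags is None else lags)

    def _estimable_cells(self) -> list:
        """Cells with at least 3 frames (two velocity samples)."""
        return [c for c in self.traj.cell_ids if self.traj.positions(c)[0].size >= 3]


class _BaseResults:
    """Shared Results behaviour: parameter table and summary rendering."""

    def _rows(self) -> list[tuple[str, str, str]]:  # (name, value, stderr)
        raise NotImplementedError

    def summary(self) -> str:
        title = f"{self.model.__class__.__name__} fit ({self.model.name})"
        lines = [title, "=" * len(title),
                 f"{'parameter':<22}{'estimate':>14}{'std err':>12}"]
        for name, value, se in self._rows():
            lines.append(f"{name:<22}{value:>14}{se:>12}")
        lines.append(f"{'n_cells':<22}{self.model.traj.n_cells:>14}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# homogeneous PRW


@dataclass
class HomogeneousResults(_BaseResults):
    model: "HomogeneousModel"
    prw: est.PRWFit
    integration_dt: float

    @property
    def params(self) -> dict:
        return {"S": self.prw.S, "P": self.prw.P, "sigma_err": self.prw.sigma_err}

    @property
    def bse(self) -> np.ndarray:
        return self.prw.bse

    def _rows(self):
        se = self.prw.bse if self.prw.bse is not None else [np.nan] * 3
        return [
            ("S (μm/min)", f"{self.prw.S:.4f}", f"{se[0]:.4f}"),
            ("P (min)", f"{self.prw.P:.2f}", f"{se[1]:.2f}"),
            ("sigma_err (μm)", f"{self.prw.sigma_err:.3f}", f"{se[2]:.3f}"),
        ]

    def simulate(
        self, seed: int, n_cells=None, duration=None, with_error=True
    ) -> TrajectoryTable:
        n = n_cells or self.model.traj.n_cells
        dur = duration or self.model.max_duration()
        params = sim.HOParams(
            self.prw.S, self.prw.P, self.prw.sigma_err,
            self.integration_dt, self.model.base_dt(),
        )
        traj = sim.simulate_ho(params, n, dur, seed)
        if with_error and self.prw.sigma_err > 0:
            traj = sim.add_localization_error(traj, self.prw.sigma_err, seed + 1)
        return traj


class HomogeneousModel(_BaseModel):
    """Classic persistent random walk: one (S, P, σ_err) for the whole cohort."""

    name = "ho"

    def fit(self, exclude_lags=(), integration_dt: float = 0.01) -> HomogeneousResults:
        prw = est.fit_prw_msd(self.observed_msd(), exclude_lags=exclude_lags)
        return HomogeneousResults(self, prw, integration_dt)


# ---------------------------------------------------------------------------
# cellular heterogeneity


@dataclass
class CellHeterogeneousResults(_BaseResults):
    model: "CellHeterogeneousModel"
    percell: est.PerCellEstimates
    sigma_err: float
    integration_dt: float

    @property
    def params(self) -> dict:
        return {
            "S_i": self.percell.S_i, "P_i": self.percell.P_disc,
            "sigma_err": self.sigma_err,
        }

    def _rows(self):
        S, P = self.percell.S_i, self.percell.P_disc
        return [
            ("mean S_i (μm/min)", f"{S.mean():.4f}", f"{S.std(ddof=1)/np.sqrt(S.size):.4f}"),
            ("median P_i (min)", f"{np.median(P):.1f}", ""),
            ("sigma_err (μm)", f"{self.sigma_err:.3f}", ""),
            ("flagged cells", f"{int(self.percell.flagged.sum())}", ""),
        ]

    def simulate(self, seed: int, duration=None, with_error=True) -> TrajectoryTable:
        dur = duration or self.model.max_duration()
        params = sim.CHParams(
            self.percell.S_i, self.percell.P_disc, self.sigma_err,
            self.integration_dt, self.model.base_dt(),
        )
        traj = sim.simulate_ch(params, dur, seed)
        if with_error and self.sigma_err > 0:
            traj = sim.add_localization_error(traj, self.sigma_err, seed + 1)
        return traj


class CellHeterogeneousModel(_BaseModel):
    """Per-cell PRW: each cell gets its own (S_i, P_i) estimated from its track."""

    name = "ch"

    def fit(self, sigma_err=None, integration_dt: float = 0.01) -> CellHeterogeneousResults:
        if sigma_err is None:
            sigma_err = est.fit_prw_msd(self.observed_msd()).sigma_err
        percell = est.estimate_percell(self.traj.subset(self._estimable_cells()))
        return CellHeterogeneousResults(self, percell, sigma_err, integration_dt)


# ---------------------------------------------------------------------------
# temporal heterogeneity


@dataclass
class TemporalResults(_BaseResults):
    model: "TemporalModel"
    A_th: float
    sampler: est.DisplacementSampler
    step_dt: float
    sigma_err: float
    calibration: est.MemoryCalibration = field(repr=False, default=None)

    @property
    def params(self) -> dict:
        return {"A_th": self.A_th, "step_dt": self.step_dt, "sigma_err": self.sigma_err}

    def _rows(self):
        return [
            ("A_th", f"{self.A_th:.3f}", ""),
            ("step_dt (min)", f"{self.step_dt:.0f}", ""),
            ("sigma_err (μm)", f"{self.sigma_err:.3f}", ""),
            ("beta source size", f"{self.sampler.magnitudes.size}", ""),
        ]

    def simulate(self, seed: int, n_cells=None, duration=None, with_error=True):
        n = n_cells or self.model.traj.n_cells
        dur = duration or self.model.max_duration()
        params = sim.THParams(self.A_th, self.sampler, n, dur, self.step_dt)
        traj = sim.simulate_th(params, seed)
        if with_error and self.sigma_err > 0:
            traj = sim.add_localization_error(traj, self.sigma_err, seed + 1)
        return traj


class TemporalModel(_BaseModel):
    """Temporal-noise walk with a shared step-magnitude sampler.

    The step grid is the cohort persistence time snapped to the sampling
    interval; β is sampled from the observed ensemble displacement
    distribution at that lag; the memory parameter A is calibrated by
    replicate-averaged MSD matching against the observed MSD.
    """

    name = "th"

    def fit(
        self,
        step_dt=None,
        sigma_err=None,
        n_replicates: int = 50,
        seed: int = 0,
        sampler_seed: int = 1,
    ) -> TemporalResults:
        prw = est.fit_prw_msd(self.observed_msd())
        if sigma_err is None:
            sigma_err = prw.sigma_err
        if step_dt is None:
            step_dt = est.discretize_persistence(prw.P, self.base_dt())
        sampler = est.build_displacement_sampler(
            self.traj, step_dt, scope="ensemble", seed=sampler_seed
        )
        dur = self.max_duration()
        cal = est.calibrate_memory(
            self.observed_msd(), sampler, step_dt, model="th",
            n_cells=self.traj.n_cells, duration=dur, n_replicates=n_replicates,
            seed=seed, sigma_err=sigma_err,
        )
        return TemporalResults(self, cal.A, sampler, float(step_dt), sigma_err, cal)


# ---------------------------------------------------------------------------
# combined heterogeneity


@dataclass
class CombinedResults(_BaseResults):
    model: "CombinedModel"
    A_cth: float
    samplers: list
    P_i: np.ndarray
    sigma_err: float
    calibration: est.MemoryCalibration = field(repr=False, default=None)

    @property
    def params(self) -> dict:
        return {"A_cth": self.A_cth, "P_i": self.P_i, "sigma_err": self.sigma_err}

    def _rows(self):
        return [
            ("A_cth", f"{self.A_cth:.3f}", ""),
            ("median P_i (min)", f"{np.median(self.P_i):.1f}", ""),
            ("sigma_err (μm)", f"{self.sigma_err:.3f}", ""),
        ]

    def simulate(self, seed: int, duration=None, with_error=True):
        dur = duration or self.model.max_duration()
        params = sim.CTHParams(self.A_cth, self.P_i, self.samplers, dur)
        traj = sim.simulate_cth(params, seed)
        if with_error and self.sigma_err > 0:
            traj = sim.add_localization_error(traj, self.sigma_err, seed + 1)
        return traj


class CombinedModel(_BaseModel):
    """Cellular and temporal heterogeneity: per-cell step grids and samplers."""

    name = "cth"

    def fit(
        self,
        sigma_err=None,
        n_replicates: int = 50,
        seed: int = 0,
        sampler_seed: int = 1,
    ) -> CombinedResults:
        if sigma_err is None:
            sigma_err = est.fit_prw_msd(self.observed_msd()).sigma_err
        percell = est.estimate_percell(self.traj.subset(self._estimable_cells()))
        samplers = [
            est.build_displacement_sampler(self.traj, P, scope=cid,
                                           seed=sampler_seed + k)
            for k, (cid, P) in enumerate(zip(percell.cell_ids, percell.P_disc))
        ]
        dur = self.max_duration()
        cal = est.calibrate_memory(
            self.observed_msd(), samplers, percell.P_disc, model="cth",
            duration=dur, n_replicates=n_replicates, seed=seed, sigma_err=sigma_err,
        )
        return CombinedResults(self, cal.A, samplers, percell.P_disc, sigma_err, cal)


MODEL_CLASSES = {
    "ho": HomogeneousModel,
    "ch": CellHeterogeneousModel,
    "th": TemporalModel,
    "cth": CombinedModel,
}
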