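"""End-to-end analysis: observe → estimate → simulate → compare.

``run_full_comparison`` runs the whole study on one cohort: it loads (or
synthesizes) an observed trajectory table, fits the four migration models to
it, simulates a replicate ensemble of every fitted model with localization
error applied, and scores each model against the observation by

* a χ² p-value of the observed ensemble MSD against the replicate ensemble
  (excluding configured lags, by default the first sampling interval),
* the RMSLE between the model's and the observation's van Hove function
  G(r, t) at the configured lags,
* the non-Gaussian parameter α₂ of ensemble displacements at those lags.

Everything is a pure function of the config (explicit seeds, no wall-clock
state). Step-based models only carry statistics at lags commensurate with a
cell's step grid; incommensurate cells are skipped at that lag, not
interpolated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import statistics as stats
from .comparison import ComparisonReport, EnsembleSummary, chi2_pvalue, rmsle, non_gaussian_parameter
from .models import MODEL_CLASSES
from .synthetic import gen_reference_cohort
from .trajectories import TrajectoryTable, read_trajectories, write_trajectories

__all__ = ["PipelineConfig", "PipelineError", "run_full_comparison"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Configuration of the full comparison; all randomness via ``seed``."""

    scenario: str | None = None  # homogeneous | cellular | temporal | combined
    trajectory_path: str | None = None  # alternative to scenario
    sampling_dt: float = 34.0  # min
    lags_G: tuple = (68.0, 408.0)  # min, lags for G(r, t) comparisons
    exclude_lags: tuple = (34.0,)  # min, dropped from the chi² statistic
    models: tuple = ("ho", "ch", "th", "cth")
    n_replicates: int = 50
    seed: int = 0
    integration_dt: float = 0.01  # min, OU integration step
    bin_width: float = 2.5  # μm, radial bin width for G and g_i
    n_cells: int | None = None  # synthetic scenarios only
    duration: float | None = None  # min, synthetic scenarios only
    outdir: str | None = None
    figures: bool = False

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.trajectory_path is None):
            raise ValueError("exactly one of scenario / trajectory_path is required")
        for lag in self.lags_G:
            if abs(lag / self.sampling_dt - round(lag / self.sampling_dt)) > 1e-9:
                raise ValueError(f"lag {lag} is not a multiple of sampling_dt")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("lags_G", "exclude_lags", "models"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in
            np.random.SeedSequence(seed).spawn(n)]


def run_full_comparison(config: PipelineConfig) -> ComparisonReport:
    """Execute the full observe→estimate→simulate→compare pipeline."""
    written: list[Path] = []
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    def emit(name: str, writer) -> None:
        if outdir:
            path = outdir / name
            writer(path)
            written.append(path)

    stage = "input"
    try:
        seed_input, seed_fit, seed_sim = _spawn_seeds(config.seed, 3)
        if config.scenario is not None:
            observed, _pop = gen_reference_cohort(
                config.scenario, seed_input, n_cells=config.n_cells,
                duration=config.duration, integration_dt=config.integration_dt,
            )
        else:
            observed = read_trajectories(config.trajectory_path)
        emit("observed.csv", lambda p: write_trajectories(observed, p))

        stage = "estimation"
        obs_lags = None
        fitted = {}
        for k, name in enumerate(config.models):
            model = MODEL_CLASSES[name](observed)
            if name in ("th", "cth"):
                fitted[name] = model.fit(
                    n_replicates=config.n_replicates, seed=seed_fit + k
                )
            elif name == "ho":
                fitted[name] = model.fit(integration_dt=config.integration_dt)
            else:
                fitted[name] = model.fit(integration_dt=config.integration_dt)
            if obs_lags is None:
                obs_lags = model.observed_lags()
        observed_msd = stats.msd(observed, obs_lags)

        stage = "simulation"
        replicates = {}
        for k, name in enumerate(config.models):
            rep_seeds = _spawn_seeds(seed_sim + k, config.n_replicates)
            replicates[name] = [fitted[name].simulate(rs) for rs in rep_seeds]

        stage = "statistics"
        report = ComparisonReport(
            models={}, lags=list(config.lags_G), exclude_lags=list(config.exclude_lags)
        )
        obs_G = {}
        for lag in config.lags_G:
            max_r = max(
                [stats.displacements(observed, lag).max()]
                + [stats.displacements(t, lag).max()
                   for reps in replicates.values() for t in reps]
            )
            edges = stats.default_bin_edges(max_r, config.bin_width)
            obs_G[lag] = stats.self_correlation_ensemble(observed, lag, edges)
        emit("observed_msd.csv", lambda p: observed_msd.to_dataframe().to_csv(p, index=False))

        stage = "comparison"
        for name in config.models:
            # step-based models only reach lags commensurate with a cell's grid
            rep0 = replicates[name][0]
            usable = []
            for lag in obs_lags:
                for cid in rep0.cell_ids:
                    m = lag / rep0.dt(cid)
                    if (abs(m - round(m)) < 1e-9 and m >= 1
                            and lag <= rep0.duration(cid) + 1e-9):
                        usable.append(lag)
                        break
            curves = [stats.msd(t, np.asarray(usable)) for t in replicates[name]]
            ensemble = EnsembleSummary.from_curves(curves)
            chi2, dof, p = chi2_pvalue(observed_msd, ensemble, config.exclude_lags)
            entry = {"chi2": chi2, "dof": dof, "p_value": p,
                     "rmsle_G": {}, "alpha2_G": {}, "alpha2_observed": {}}
            for lag in config.lags_G:
                edges = obs_G[lag].bin_edges
                model_G = np.mean(
                    [stats.self_correlation_ensemble(t, lag, edges).densities
                     for t in replicates[name]], axis=0,
                )
                entry["rmsle_G"][str(lag)] = rmsle(model_G, obs_G[lag].densities)
                pooled = np.concatenate(
                    [stats.displacements(t, lag) for t in replicates[name]]
                )
                entry["alpha2_G"][str(lag)] = non_gaussian_parameter(pooled)
                entry["alpha2_observed"][str(lag)] = non_gaussian_parameter(
                    stats.displacements(observed, lag)
                )
            if name == "ho":
                entry["params"] = {k: float(v) for k, v in fitted[name].params.items()}
            report.models[name] = entry

        stage = "output"
        emit("report.json", lambda p: p.write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True)
        ))
        if outdir and config.figures:
            _write_figures(outdir, observed_msd, obs_G, written)
        return report
    except Exception as exc:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise PipelineError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _write_figures(outdir: Path, observed_msd, obs_G, written: list) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.errorbar(observed_msd.lags, observed_msd.values, yerr=observed_msd.sem,
                fmt="o", ms=3, label="observed")
    ax.set_xlabel("lag (min)")
    ax.set_ylabel("MSD (μm²)")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.legend()
    path = outdir / "msd.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    for lag, curve in obs_G.items():
        fig, ax = plt.subplots()
        ax.semilogy(curve.bin_centers, curve.densities, "o", ms=3)
        ax.set_xlabel("r (μm)")
        ax.set_ylabel(f"G(r, t={lag:g} min) (μm⁻²)")
        path = outdir / f"G_{lag:g}min.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
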