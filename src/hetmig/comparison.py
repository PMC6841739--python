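"""Quantitative model ranking.

* χ² goodness of fit of an observed ensemble MSD against a simulation
  ensemble: χ² = Σ (obs − mean)²/std² over the included lags, with the
  per-lag mean and standard deviation taken across replicate simulations and
  the upper-tail χ² probability as p-value. Degrees of freedom equal the
  number of included lags (no parameter-count correction — the model
  parameters are estimated from the same data, which this diagnostic does not
  attempt to correct for).
* RMSLE (root mean-squared logarithmic error) between two non-negative
  curves, natural logarithm of (value + 1).
* The non-Gaussian parameter α₂ = ⟨r⁴⟩/(2⟨r²⟩²) − 1 of a set of 2-D
  displacement magnitudes (zero for Gaussian displacements, −0.5 for
  fixed-length steps, positive for heavy-tailed mixtures).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .statistics import MSDCurve

__all__ = [
    "EnsembleSummary",
    "ComparisonReport",
    "chi2_pvalue",
    "rmsle",
    "non_gaussian_parameter",
]


@dataclass
class EnsembleSummary:
    """Per-lag mean and sample standard deviation of MSD over replicates."""

    lags: np.ndarray
    mean: np.ndarray
    std: np.ndarray  # ddof=1 across replicates
    n_replicates: int

    @classmethod
    def from_curves(cls, curves: list[MSDCurve]) -> "EnsembleSummary":
        if len(curves) < 2:
            raise ValueError("need at least 2 replicate curves")
        lags = curves[0].lags
        for c in curves[1:]:
            if not np.array_equal(c.lags, lags):
                raise ValueError("replicate curves must share lags")
        vals = np.stack([c.values for c in curves])
        return cls(lags, vals.mean(axis=0), vals.std(axis=0, ddof=1), len(curves))


def chi2_pvalue(
    observed: MSDCurve, ensemble: EnsembleSummary, exclude_lags=()
) -> tuple[float, int, float]:
    """χ² of an observed MSD against a simulation ensemble; returns (χ², dof, p)."""
    excl = {round(float(l), 6) for l in exclude_lags}
    common = [
        (i, int(np.flatnonzero(np.isclose(ensemble.lags, lag))[0]))
        for i, lag in enumerate(observed.lags)
        if round(float(lag), 6) not in excl
        and lag > 0
        and np.any(np.isclose(ensemble.lags, lag))
    ]
    if not common:
        raise ValueError("observed and ensemble share no usable lags")
    chi2 = 0.0
    for i_obs, i_ens in common:
        std = ensemble.std[i_ens]
        if std <= 0:
            raise ValueError(
                f"ensemble standard deviation is zero at lag {ensemble.lags[i_ens]} min"
            )
        chi2 += float((observed.values[i_obs] - ensemble.mean[i_ens]) ** 2 / std**2)
    dof = len(common)
    p = float(sps.chi2.sf(chi2, dof))
    return chi2, dof, p


def rmsle(c, c_hat) -> float:
    """√(mean of (log(c+1) − log(ĉ+1))²), natural log; symmetric in its arguments."""
    c = np.asarray(c, dtype=float)
    c_hat = np.asarray(c_hat, dtype=float)
    if c.shape != c_hat.shape:
        raise ValueError(f"shape mismatch: {c.shape} vs {c_hat.shape}")
    if np.any(c < 0) or np.any(c_hat < 0):
        raise ValueError("RMSLE inputs must be non-negative")
    d = np.log1p(c) - np.log1p(c_hat)
    return float(np.sqrt(np.mean(d**2)))


def non_gaussian_parameter(displacement_magnitudes) -> float:
    """α₂ = ⟨r⁴⟩/(2⟨r²⟩²) − 1 (2-D convention) of displacement magnitudes."""
    r = np.asarray(displacement_magnitudes, dtype=float)
    if r.size < 10:
        raise ValueError(f"need at least 10 displacement magnitudes, have {r.size}")
    m2 = np.mean(r**2)
    if m2 == 0:
        raise ValueError("all displacements are zero; α₂ undefined")
    return float(np.mean(r**4) / (2.0 * m2**2) - 1.0)


@dataclass
class ComparisonReport:
    """Per-model goodness-of-fit summary produced by the pipeline."""

    models: dict = field(default_factory=dict)  # name -> dict of statistics
    lags: list = field(default_factory=list)
    exclude_lags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "lags": list(map(float, self.lags)),
            "exclude_lags": list(map(float, self.exclude_lags)),
        }
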