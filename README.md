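# hetmig — stochastic and heterogeneous 2-D cell migration

`hetmig` is a toolkit for analysing and simulating two-dimensional single-cell
migration in the presence of **population heterogeneity**. It is aimed at
quantitative cell biologists and biophysicists who track cells (e.g. cancer
cell lines under time-lapse microscopy) and want to ask *why* the ensemble
displacement statistics of a genetically homogeneous population are
non-Gaussian: because cells differ from each other (**cellular
heterogeneity**), because each cell switches migration states over time
(**temporal heterogeneity**), or both.

## The models

The baseline is the persistent random walk (PRW): each velocity component is
an Ornstein–Uhlenbeck process

    dv/dt = −v/P + (S/√P) dW,

with persistence time `P` (min) and speed scale `S` (μm/min), giving the
two-dimensional mean-square displacement

    ⟨(Δr)²(t)⟩ = 2S²P² (e^(−t/P) + t/P − 1) + 4σ_err²,

where `σ_err` is the localization error of the position measurement. On top
of this the package implements four cohort models, fitted to data through a
statsmodels-style Model/Results interface:

| key  | class                    | heterogeneity                             |
|------|--------------------------|-------------------------------------------|
| `ho` | `HomogeneousModel`       | none: one (S, P) for every cell            |
| `ch` | `CellHeterogeneousModel` | per-cell (S_i, P_i) from each track        |
| `th` | `TemporalModel`          | time-varying step magnitude β(t), shared   |
| `cth`| `CombinedModel`          | per-cell β_i(t) and per-cell step grids    |

The step-based models (`th`, `cth`) draw β by inverse-transform sampling from
the *empirical* displacement distribution 2πr·G(r, t=P) (or its per-cell
analogue 2πr·g_i(r, t=P_i)) and carry a geometric memory of the previous
displacement, dr(t+dt) = dr(t)/A + β(t)·ξ, with the memory parameter `A`
calibrated by matching the replicate-averaged simulated MSD to the observed
one.

Model discrimination uses the self part of the van Hove function: the
ensemble curve G(r, t), the per-cell curves g_i(r, t), their rescaled
collapse (πr*²·g_i against r/r*), the non-Gaussian parameter
α₂ = ⟨r⁴⟩/(2⟨r²⟩²) − 1, χ² p-values of the observed MSD against
50-replicate simulation ensembles, and the RMSLE between observed and
simulated curves. A weighted-centroid nucleus tracker (scores for proximity,
darkness, and rim exclusion) turns synthetic image stacks into trajectories,
and the synthetic-data module generates cohorts and image stacks emulating a
212-cell, 1292-min, 34-min-sampling time-lapse experiment.

## Worked example

```python
import hetmig as hm

# a synthetic homogeneous cohort at the canonical design:
# 212 cells, 1292 min, 34-min sampling, S = 0.125 μm/min, P = 78 min,
# localization error 1.66 μm
traj, truth = hm.gen_reference_cohort("homogeneous", seed=7, n_cells=212)

model = hm.HomogeneousModel(traj)
result = model.fit()
print(result.summary())
```

prints

```
HomogeneousModel fit (ho)
=========================
parameter                   estimate     std err
S (μm/min)                    0.1272      0.0004
P (min)                        69.70        0.59
sigma_err (μm)                 1.636       0.009
n_cells                          212
```

The fit recovers the generating speed scale (0.127 vs 0.125 μm/min) and
localization error (1.64 vs 1.66 μm); the persistence estimate (69.7 vs
78 min) carries the expected ~10 % sampling scatter of a single 212-cell
cohort. Ensemble statistics come from the same objects:

```python
curve = model.observed_msd([34.0, 68.0, 408.0])
# MSD(34 min) = 26.8 μm², MSD(68 min) = 65.7 μm², MSD(408 min) = 775.4 μm²
hm.non_gaussian_parameter(hm.displacements(traj, 68.0))
# -0.019  → Gaussian, as a homogeneous PRW cohort must be
```

`result.simulate(seed)` returns a synthetic cohort of the fitted model at
the observed design, and `hetmig.run_full_comparison(PipelineConfig(...))`
runs the whole observe → estimate → simulate → compare pipeline, producing a
JSON report with per-model χ² p-values, RMSLE values and α₂ diagnostics.
The same stages are scriptable from the shell:

```sh
hetmig synth --scenario combined --seed 3 --out traj.csv
hetmig fit --traj traj.csv --model prw --out params.yaml
hetmig stats --traj traj.csv --what msd,G --lags 68,408 --out-dir curves/
hetmig run --config pipeline.yaml
```

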