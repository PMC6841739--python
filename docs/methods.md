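# Methods

## Models

All four cohort models describe independent cells moving in two dimensions.

**Homogeneous PRW (`ho`).** Each velocity component is an Ornstein–Uhlenbeck
process dv/dt = −v/P + (S/√P)dW. The stationary per-component variance is
S²/2, so the stationary mean-square speed is S². The 2-D MSD is
2S²P²(e^(−t/P) + t/P − 1), plus a 4σ_err² floor when positions carry
measurement noise. Assumptions: stationarity (no slowing down or speeding up
over the observation window), isotropy, no cell–cell interaction, no drift.

**Cell-heterogeneous PRW (`ch`).** The same dynamics with a per-cell pair
(S_i, P_i). Each cell's displacement distribution stays Gaussian; the
ensemble van Hove function G(r, t) becomes a variance mixture and hence
non-Gaussian whenever the (S_i, P_i) spread is non-degenerate.

**Temporal-noise walk (`th`).** Displacements live on a coarse step grid
(one step per discretized persistence time). Each step is
dr(t+dt) = dr(t)/A + β(t)·ξ with ξ uniform on the circle and β freshly drawn
every step from an empirical step-length distribution. A single sampler and
step length are shared by all cells, so cells are statistically identical
(G = g_i) but individually non-Gaussian when the β distribution is.

**Combined walk (`cth`).** As `th`, but cell i has its own step length P_i
and its own sampler; both ensemble and per-cell statistics are non-Gaussian
and per-cell curves differ across cells.

## Parameters

| parameter | units | default | role |
|---|---|---|---|
| S | μm/min | 0.125 | PRW speed scale (canonical cohort value) |
| P | min | 78 | PRW persistence time |
| σ_err | μm | 1.66 | localization error; adds 4σ_err² to the MSD |
| Δt | min | 34 | sampling interval of the emulated experiment |
| τ | min | 1292 | observation window (39 frames) |
| N | — | 212 | cohort size |
| h | min | 0.01 | OU integration step (h ≪ P) |
| A | — | ~2.4–2.5 | step-walk memory; exp(h/P) analogue in the OU picture |
| step_dt | min | 68 | discretized persistence: 78 min snapped to the 34-min grid |

The canonical values are the study design the synthetic cohorts emulate; the
integration step is small enough that the Euler position quadrature error is
O(h/P) ≈ 10⁻⁴.

## Numerical choices

* **OU integration** uses the exact discrete update
  v ← v·e^(−h/P) + √((1−e^(−2h/P))·S²/2)·N(0,1) per component (an AR(1)
  recursion evaluated in C via `scipy.signal.lfilter`), positions by Euler
  accumulation. Initial velocities are drawn from the stationary law, so
  there is no equilibration transient; initial positions sit at the origin
  (all statistics are displacement-based).
* **Step walks**: the first step carries no memory term (no displacement is
  defined before t = 0). Randomness is consumed in a documented order
  (magnitude uniforms, then direction uniforms) so a scalar step-by-step
  reference reproduces the production output bit-for-bit at equal seeds.
* **Localization error** is injected on sampled positions only, as
  independent N(0, σ_err²) per coordinate — the way measurement noise enters
  an experiment, not the dynamics.
* **Displacement samplers** use the sample quantile function with linear
  interpolation between order statistics; draws are confined to the source
  range. A binned-histogram CDF would add bin-width sensitivity for no gain.
* **PRW MSD fit**: nonlinear least squares over (S, P, σ_err) with
  positivity bounds and nine deterministic starts (three persistence guesses
  × three scale perturbations). Residuals are weighted by the curve's
  per-lag SEM when available; this is what pins down the small σ_err offset
  from the precisely determined short lags. Reported standard errors come
  from the Gauss–Newton approximation and ignore the strong correlation of
  MSD values across lags, so they are optimistic; the robustness check
  (dropping the first lag) is therefore expressed in relative parameter
  shifts.
* **Persistence discretization** maps a continuous decay time to the nearest
  positive multiple of the sampling interval (78 → 68 at Δt = 34, half-way
  rounds up, minimum one interval). The step-based models need step lengths
  commensurate with the sampling grid.
* **Per-cell estimation**: P_i is the first downward 1/e crossing of the
  cell's normalized VACF, located by linear interpolation between bracketing
  lags (single-cell VACFs are noisy and may recross; the first crossing is
  the operational decay time). Cells whose VACF never crosses are flagged
  and assigned the maximum observed lag. S_i is the time-mean secant speed.
* **Memory calibration** minimizes a weighted mean of squared *log*-MSD
  deviations between the replicate-averaged simulation (50 replicates by
  default, fixed inner seeds, so the objective is a smooth deterministic
  function of A) and
  the reference curve, searched over A ∈ [1.01, 20] by bounded scalar
  minimization. The log scale balances short, well-determined lags against
  long, noisy ones; weights proportional to the number of cells contributing
  to each lag keep sparsely populated lags (per-cell step grids) from
  dominating the noise. When the reference was measured with localization
  error, the expected 4σ_err² floor is added to the simulated MSD rather
  than re-noising every replicate.
* **Commensurate-lag rule**: statistics at a lag include a cell only when
  the lag is a whole multiple of that cell's grid and within its duration —
  no interpolation. This is the only unbiased option for the step-based
  models, at the cost of uneven cell counts per lag (reported alongside each
  MSD value).
* **Van Hove histograms** use 2.5-μm radial bins by default (half a pixel;
  fine enough to resolve the r ≲ 4r* tails, coarse enough for ≥10 counts
  per bin at N = 212). The annulus normalization is exact because
  π(r_hi² − r_lo²) = 2π·r_mid·Δr. Rescaled curves are binned at 0.25 in
  r/r* units. Speed bins for the acceleration decomposition are 0.05 μm/min
  wide; bins under 10 samples are meant to be filtered via
  `AccelerationStats.filtered`.
* **Tracker**: the normalizing constants of the proximity and darkness
  scores cancel in the weighted centroid and are set to 1. Coordinates are
  0-based pixel-centred; exported μm positions are pixel values × 5 μm,
  rounded to 1/10 pixel (0.5 μm). If every score in a window is zero the
  track is truncated and flagged — no re-seeding. Nearby cells are scored
  independently; no exclusion rule arbitrates overlapping windows.

## Finite-sampling effects worth knowing about

* Velocities estimated as position differences over Δt = 34 min are *secant*
  velocities. Their autocorrelation at one lag is
  ρ = (1−a)²/(2(a + Δt/P − 1)) with a = e^(−Δt/P) (≈ 0.75 for P = 78),
  not e^(−Δt/P) (≈ 0.65), and as Δt → 0 the implied decay rate tends to
  2/(3P), not 1/P. Consequently the VACF-crossing persistence estimator
  overshoots P without localization error and undershoots with it, and the
  speed-conditioned mean parallel acceleration has slope −(1−ρ)/Δt — of
  order −1/P but not equal to it. Closed-form checks of the OU model are
  therefore run on the simulator's exact velocity states; estimator checks
  use wide, honest tolerances.
* Per-cell non-Gaussian parameters from ~20–40 displacements are biased
  downward (a few tenths), so per-cell Gaussianity judgements always compare
  against simulations at the same design rather than against zero.
* Resampling a step distribution through an interpolated empirical inverse
  CDF built from few source points compresses the tails; a combined-model
  refit of its own cohort therefore shows somewhat lighter per-cell tails
  than the cohort itself. Comparisons between fitted models remain valid
  because all models share the handicap.
* The χ² MSD diagnostic treats lags as independent, but MSD values of one
  cohort are strongly correlated across lags; the p-value is calibrated
  lag-wise (uniform under the true model at a single lag, mean χ² equal to
  the number of lags) while the joint statistic is over-dispersed. Degrees
  of freedom are the number of included lags with no parameter-count
  correction, since the parameters are estimated from the same data.

## Synthetic data

The generator emulates the statistical structure of a 212-cell, 24-h
time-lapse experiment: per-cell speeds and persistences are log-normal
(medians 0.125 μm/min and 78 min, log-scale spreads 0.35 and 0.4 — positive
support and right skew; the true per-cell values of any given experiment are
not published, so these are stand-ins chosen to give a clearly heterogeneous
cohort). Persistences are snapped to the sampling grid at generation.
Temporal heterogeneity in the reference scenarios is a two-state fast/slow
Rayleigh mixture of step magnitudes (scale ratio 3, equal occupancy,
α₂ ≈ 0.64), the standard switching picture, scaled to the PRW displacement
at one persistence time. Image stacks render each nucleus as a dark
quadratic radial profile with a brighter rim on a mid-brightness background
(the contrast polarity the tracker's darkness and rim-exclusion scores
require), plus i.i.d. clipped Gaussian pixel noise, at 5 μm/pixel and 2-min
frames.

What the generator does **not** emulate: phase-contrast optics, cell
division, collisions, shape dynamics and segmentation artefacts, drift or
chemotaxis, 3-D motion, and any slow non-stationarity of migration
statistics. Passing tests demonstrate correctness of the estimators and the
internal consistency of the model chain at a realistic design — not that any
particular laboratory cohort follows one of these models.

## Test and calibration problem sizes

Closed-form OU checks run on 10⁴-cell cohorts with a 0.1-min integration
step; parameter-recovery checks use 500–1500 cells at the canonical design;
the qualitative four-model comparison uses a 212-cell combined cohort with
10-replicate calibrations and 5-replicate diagnostics; χ² calibration uses
reduced 80-cell, 340-min cohorts. These sizes are the package's choices,
large enough that each assertion's Monte-Carlo noise sits well inside its
tolerance.

## Known limitations

* The fitted `S` of the step-based models is implicit in the sampler; only
  `A` and the step grid are explicit parameters.
* `estimate_percell` requires ≥3 frames per cell; the model layer silently
  restricts to estimable cells (the count is visible in the Results
  summary).
* The memory search bracket [1.01, 20] covers the persistent regime; a truly
  memoryless reference calibrates to the bracket edge unless the caller
  widens `bounds` (memory still inflates the MSD by ~2/A at the default
  upper edge).
* Lost tracks are effectively unreachable with the default score functions
  (the previous-position pixel always scores positively); the truncation
  path exists for pathological inputs.
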