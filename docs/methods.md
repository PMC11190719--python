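# Methods

This note documents the models, conventions and design choices behind
`lymphokinetics`, in the order of the pipeline.

## Lymphocyte-depletion model

ALC during radiotherapy is modelled per patient as
`ALC(t) = a·exp(−b·t) + c` with `a, c ≥ 0` (counts cannot be negative)
and `t` in days from the first fraction.  The model captures the fast
initial kill of the highly radiosensitive circulating pool and the
plateau maintained by production and redistribution.

**Baseline.**  The count closest to the start of radiotherapy, no older
than 91 days ("three months" implemented as an unambiguous integer) and
no later than day 2, is the baseline `ALC₀`.  Distance ties are broken
toward the later count.  A pre-treatment baseline is mapped to `t = 0`
for fitting, since it estimates the day-0 state.

**Fitting.**  Bounded trust-region least squares
(`scipy.optimize.least_squares`, tolerances 1e-10, at most 1,000
evaluations, analytic Jacobian) on all counts in `[0, window]`, window
45 days by default.  Same-day duplicates are averaged to avoid implicit
weighting.  Initial values are literature-scale kinetics: rate 0.10/day,
plateau 0.34×10³/µL, `a₀ = max(ALC₀ − 0.34, 0.01)`.  The rate `b` is
deliberately left *unconstrained* during optimization and range-checked
afterwards: constraining it would convert implausible kinetics into
silent boundary fits instead of counted QC failures.

**Fit QC.**  Mutually exclusive statuses, assigned in this order: fewer
than three usable points → `fail_insufficient_points`; optimizer hit the
evaluation cap → `fail_no_converge`; `b < 0` or `b > 1` (with 1e-8
numerical slack so a perfect flat fit with `b = −1e-11` is not
misclassified) → `fail_b_range`; R² < 0.5 → `fail_r2`; otherwise
`success`.  For the nonlinear fit R² is `1 − SS_res/SS_tot` about the
observed mean; a constant series (`SS_tot = 0`) is defined to have
R² = 1 when the residuals vanish and 0 otherwise, making the degenerate
case deterministic.

**Endpoint.**  Percentage ALC loss
`100·(1 − AUC(0→T)/(ALC₀·T))` with the closed form
`AUC = a/b·(1 − e^{−bT}) + c·T` (limit `(a+c)·T` as `b → 0`).  `T` is
the time of the *last count inside the window*, not the window length:
the fitted curve is only trusted where data exist.  A negative loss
(curve above baseline) is reported with a QC flag, never clamped.  The
nadir is the lowest observed in-window count; CTCAE lymphopenia grades
are 4/3/2/1 below 0.2/0.5/0.8/LLN (LLN configurable, default
1.0×10³/µL), grade ≥ 3 defining severe RIL.

## Dosimetry

Cumulative DVH records carry Dmin/Dmean/Dmax and the volume grid
V0.5, V1, V2, V5 … V55 Gy (percent of structure volume receiving at
least the threshold).  Thresholds are absolute Gy: the enumerated grid
makes that the only consistent unit.  Validation checks volume range,
monotonicity along the grid and `Dmin ≤ Dmean ≤ Dmax`; the validator
reports named issues and never throws.

**EQD2.**  `EQD2 = D·(d + α/β)/(2 + α/β)` with `α/β = 10` Gy for all
structures.  For a cumulative-DVH point with threshold dose `D` the dose
per fraction is taken as `d = D/n` (uniform fractionation; the plan's
fraction count is the only fractionation datum).  The transform is
strictly increasing in `D`, so the dose axis is warped point-wise and
volumes are resampled onto the standard grid by linear interpolation on
the (dose, volume) polyline — the standard cDVH convention, which
preserves monotonicity — carried flat at 100 % below the lowest
transformed threshold and 0 % above the highest.

**EDRIC.**  `0.12·MLD + 0.08·MHD + (0.45 + 0.35·0.85·(n/45))·MBD`,
where MLD/MHD/MBD are mean lung (sum), heart and body doses; the body
term grows with the fraction number `n` because each fraction
re-irradiates circulating blood.  The weights are exposed as keyword
arguments for sensitivity analyses.  EDRIC is computed from physical
mean doses.

## Association pipeline

Only patients with a successful fit enter the complete-case analysis
table.

* **Univariable screen:** per metric and technique stratum, OLS
  `%loss ~ CRT + metric`, reporting the model R².  CRT is kept in every
  screen model because it is the dominant clinical driver of depletion.
  Zero-variance metrics are flagged degenerate rather than fatal.  No
  multiplicity correction — the screen ranks R², it does not test.
* **ANCOVA plan comparison:** per metric, `metric ~ technique + PTV`,
  extracting the VMAT-vs-IMRT coefficient with 95 % CI and p;
  Benjamini–Hochberg adjustment is available but off by default.
* **Endpoint comparison:** Spearman correlations of each metric with
  %loss and with the nadir; the %loss endpoint should and does correlate
  more strongly when depletion is dose-driven and the nadir carries
  extra measurement-timing noise.
* **PCA:** on the correlation matrix of the metrics (they mix Gy and %,
  so standardization is obligatory), eigendecomposition via numpy.  PC1
  is sign-oriented to correlate positively with the mean body dose, so
  higher scores mean more dose-intense plans.  PTV volume is excluded by
  default (`include_ptv` toggles).
* **Multivariable models:** OLS `%loss ~ CRT + baseline ALC + (EDRIC |
  PC1)` with 95 % CIs, R², MSE = RSS/n (training-set mean squared
  prediction error), and AIC under the Gaussian convention that counts
  the error variance as a parameter
  (`n·ln 2π + n·ln(RSS/n) + n + 2(k+1)`), so ΔAIC matches mainstream
  statistical environments.  Rank-deficient designs raise an error
  naming the collinear terms.
* **Internal validation:** Harrell's optimism bootstrap, default
  B = 300 resamples of patient rows (the only sampling unit modelled),
  seeded and recorded in every report.  Each resample is refit; the
  optimism is the mean of (resample R² − R² of the resample model
  evaluated on the original table), and corrected R² = apparent −
  optimism.  The evaluated-on-original R² is the squared correlation
  between predictions and observations — the standard out-of-sample R²
  definition, identical to `1 − SSE/SST` on the training side.  With
  this convention the corrected R² is approximately zero under a null
  model; with an SSE-based test R² the procedure would over-correct
  (corrected ≈ −0.08 for n = 50, p = 3).  Degenerate resamples are
  skipped and counted, with a warning above 10 %.

## Synthetic cohort

The generator reproduces the statistical structure the analysis assumes,
with stored ground truth.

* **Covariates.**  37 % concurrent CRT, 59 % VMAT; baseline ALC
  log-normal with median 2.07×10³/µL and log-sd 0.35 (log-normal because
  counts are positive and right-skewed); PTV log-normal, median
  420 cm³; prescriptions mix 60/30, 66/33, 54/27 and 55/20
  (dose Gy/fractions).
* **Latent plan intensity.**  One standard-normal factor `z` per
  patient, half of its variance shared with log-PTV, drives every DVH
  metric and the dose effect on lymphocyte loss.  A single factor is
  deliberate: it produces the strong multicollinearity that motivates
  the PC1 summary.
* **Kinetics.**  `b` log-normal around 0.10/day (log-sd 0.30), clipped
  to [0, 1].  The target loss is linear in the covariates,
  `L = L₀ + 7.0·CRT + 8.0·z + ε`, `ε ~ N(0, 9²)` percentage points,
  with `L₀` set by a base plateau fraction of 0.36 of baseline.  The
  plateau `c` is then *solved* so the closed-form loss over the window
  equals `L` exactly, and `a = ALC₀ − c`; when a slow decay makes `L`
  unattainable (the loss ceiling is `100·(1 − (1−e^{−bT})/(bT))`), the
  rate is raised to reach it instead of clipping — intense plans deplete
  faster — keeping the configured effects exactly linear for recovery
  tests.  The CRT effect (7 pp) matches adjusted clinical estimates; the
  defaults give median loss ≈ 52 %, higher under CRT, and a median
  nadir ≈ 0.55.
* **Observations.**  Baseline drawn 0–5 days before RT plus weekly
  visits with ±2-day jitter through the whole 45-day window; counts are
  the true curve plus N(0, 0.16²) noise (≈ 8–10 % CV, realistic
  intra-patient variability), truncated at zero.  An ANC column is
  emitted (stable under RT alone, declining under CRT) but not
  analysed.
* **DVH metrics.**  `metric = mean + loading·z + correlated noise`;
  mean Vx profiles are exponential in the threshold per structure, with
  loadings ≈ 20 % of the mean (capped near the 0/100 bounds) and noise
  proportional to the loading, increasing along the grid, AR(1)-
  correlated (ρ = 0.8) across adjacent thresholds so that cumulative
  curves wiggle coherently.  Violations left by the noise are repaired
  by clipping and a pool-adjacent-violators projection, so every emitted
  record validates.  The implied population covariance is available in
  closed form (`population_metric_covariance`) and puts ≈ 50 % of
  standardized variance on the first principal component; clipping and
  repair perturb this only slightly at default noise levels.
* **Pathological series.**  8 % of patients split evenly between rising
  counts (no representable decay truth; kinetic truth fields are NaN),
  flat noisy counts (`b = 0`, plateau at baseline, inflated noise) and
  sparse sampling (two in-window counts), exercising every fit-failure
  path.  Additional failures arise naturally from measurement noise.

**What the generator does not emulate** — and hence what passing tests
do *not* show about clinical data: no centre effects or case-mix
differences, no technique differences in dosimetry unless configured
(`technique_effects`), no baseline-ALC effect on percentage loss (so the
synthetic multivariable R² ≈ 0.28–0.37 sits below values reported for
clinical cohorts where baseline ALC is predictive), no post-RT recovery,
no informative measurement timing, and DVH summaries are drawn directly
rather than derived from 3-D dose distributions.

## Numerical conventions and reproducibility

All randomness flows from one `numpy` Generator per cohort seed; equal
configuration and seed reproduce every table byte for byte, and the run
manifest records the seed, package versions and input hashes.  The AUC
closed form switches to its `b → 0` limit below |b| < 1e-12; the decay
model clips exponents at ±50 to keep rejected optimizer steps finite;
the analysis treats variances below 1e-12 as zero (degenerate).
Problem sizes used by the test-suite calibration checks — 2,000 patients
for cohort medians, 200 replicate cohorts of 250 patients for CI
coverage, 1,000 replications for the ANCOVA type-I error — were chosen
to keep Monte-Carlo error well inside the asserted bands.

## Known limitations

* The percentage-loss estimator inherits a small (< 5 %) downward
  attenuation from measurement noise interacting with the `c ≥ 0` bound
  and from evaluating at the last observed count rather than the nominal
  window end; CI coverage of the configured effects is ≈ 93–95 % rather
  than exactly nominal.
* EQD2 conversion of a cumulative DVH from summary data is approximate:
  it assumes each threshold dose is delivered uniformly over all
  fractions.
* The optimism bootstrap validates internally only; it cannot detect
  transportability failure to cohorts treated with different techniques.
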