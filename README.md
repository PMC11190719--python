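# lymphokinetics

Tools for quantifying **radiation-induced lymphopenia (RIL)** — the
depletion of circulating lymphocytes during radiotherapy — and for
linking it to the dosimetry of the treatment plan.

The package is written for radiation-oncology and biostatistics groups
analysing longitudinal absolute lymphocyte counts (ALC) together with
treatment-plan dose-volume summaries, as collected in retrospective
lung-cancer cohorts treated with IMRT or VMAT, with or without
concurrent chemoradiotherapy (CRT).

## The model

Each patient's ALC trajectory over the first 45 days from the start of
radiotherapy is fit by bounded exponential decay

```
ALC(t) = a·exp(−b·t) + c        a ≥ 0,  c ≥ 0
```

with `t` in days, `b` the depletion rate (initial value 0.10/day) and
`c` the plateau (initial value 0.34×10³/µL).  Fits are
quality-controlled (`b` outside [0, 1], R² < 0.5, fewer than three
in-window counts, or non-convergence are failures).  The endpoint is the
**percentage ALC loss** relative to baseline, computed from the area
under the fitted curve over the observation window `[0, T]`:

```
%loss = 100 · (1 − AUC(0→T) / (ALC₀ · T)),     AUC = a/b·(1−e^(−bT)) + c·T
```

This uses every available count rather than a single timepoint, and is
less sensitive to measurement timing than the lymphocyte nadir.

On the dosimetry side the package validates cumulative DVH summaries
(Dmin/Dmean/Dmax plus V0.5–V55) for the lung sum, heart and whole body,
converts doses to **EQD2** (α/β = 10 Gy), and computes **EDRIC**, the
effective dose to circulating immune cells,
`0.12·MLD + 0.08·MHD + (0.45 + 0.35·0.85·(n/45))·MBD`.

The association pipeline screens each metric (R² of
`%loss ~ CRT + metric`, by technique), compares VMAT and IMRT plans by
ANCOVA adjusted for PTV volume, contrasts Spearman correlations of the
metrics with %loss versus nadir, collapses the highly collinear metric
set to its first principal component (PC1), and fits the multivariable
models `%loss ~ CRT + baseline ALC + (EDRIC | PC1)` with
optimism-corrected R² (Harrell bootstrap, 300 resamples), MSE and AIC.

A seeded synthetic-cohort generator emulates these study conditions with
stored ground truth, so every stage is testable end to end without any
patient data.

## Worked example

```
lymphokinetics run --n 306 --seed 0 --bootstrap 300 --out run/
```

simulates a 306-patient cohort and runs every stage.  `run/report.md`
then contains, among other tables (numbers from this exact command):

```
PC1 explains 48.8 % of standardized metric variance.

## Model 2 (PC1) **(selected dose summary)**

| name | coef | ci_low | ci_high | p_value |
|---|---|---|---|---|
| intercept | 48.583 | 44.255 | 52.910 | 0.000 |
| crt | 8.394 | 5.452 | 11.336 | 0.000 |
| baseline_alc | 0.401 | -1.405 | 2.207 | 0.662 |
| pc1 | 1.520 | 1.249 | 1.792 | 0.000 |

R^2 = 0.336; bias-corrected R^2 = 0.325 (300 bootstrap resamples);
MSE = 122.0; AIC = 2088.6
```

Reading: patients on concurrent chemoradiotherapy lose about 8
percentage points more of their baseline ALC, and each unit of the PC1
dose-intensity score adds about 1.5 points; the optimism bootstrap
shrinks the apparent R² only slightly, so the model is not overfit at
this sample size.  `run/endpoints.csv` holds the per-patient fits
(status, a, b, c, R², %loss, nadir, CTCAE grade), `run/manifest.json`
the seed, versions and input hashes needed to reproduce every output
byte for byte.

The same stages run individually on your own CSV exports:
`simulate`, `endpoints`, `dvh` (validation, EQD2, EDRIC) and `analyze`
— see `lymphokinetics --help` for the file schemas expected.

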