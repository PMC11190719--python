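"""Synthetic lymphopenia cohort generator.

Emulates the data a retrospective multi-centre lymphopenia study collects
for patients irradiated for lung cancer: irregular weekly blood counts,
clinical covariates (chemoradiotherapy, technique, target volume,
prescription), and strongly collinear cumulative-DVH summaries for the
lung sum, heart and whole body.  Ground truth (per-patient decay
parameters, the latent plan-intensity factor and the implied percentage
ALC loss) is stored alongside the observations so every downstream stage
of the pipeline can be tested against known answers.

Generative model, per patient i:

* baseline ALC is log-normal around the cohort median;
* the depletion rate ``b_i`` is log-normal around 0.10/day;
* the target percentage ALC loss is linear in covariates,
  ``L_i = L0 + beta_crt * CRT_i + beta_z * z_i + eps_i``,
  where ``z_i`` is a latent plan-intensity factor (standard normal,
  partially driven by PTV size); the plateau ``c_i`` is then solved so
  the closed-form loss of ``(a_i, b_i, c_i)`` over the fit window equals
  ``L_i`` exactly, which keeps covariate effects linear for recovery
  tests;
* observed counts are the true curve at jittered weekly visits plus
  Gaussian noise, truncated at zero;
* every DVH metric is ``mean + loading * z_i + correlated noise``,
  clipped to valid ranges and projected to monotonicity, which produces
  the single-factor multicollinearity the association pipeline summarises
  with PC1.

A small configurable fraction of patients gets pathological series
(rising counts, flat noisy counts, too few in-window counts) so that each
fit-failure path is exercised.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dosimetry import (ALL_METRICS, D_METRICS, DVH_GRID, DVHRecord,
                        STRUCTURES, V_LABELS, dvh_long_from_records, v_label)
from .errors import ConfigurationError
from .kinetics import BloodCountSeries, percent_alc_loss

__all__ = [
    "CohortConfig",
    "PatientTruth",
    "Cohort",
    "StructureDVHModel",
    "default_dvh_model",
    "generate_cohort",
    "generate_dvh",
    "population_metric_covariance",
    "population_pc1_fraction",
]

PATHOLOGY_NONE = "none"
PATHOLOGY_RISING = "rising"
PATHOLOGY_FLAT = "flat"
PATHOLOGY_SPARSE = "sparse"

#: prescription (total Gy, fractions) options with sampling weights
_PRESCRIPTIONS = ((60.0, 30), (66.0, 33), (54.0, 27), (55.0, 20))
_PRESCRIPTION_P = (0.45, 0.30, 0.10, 0.15)

_PTV_MEDIAN_CM3 = 420.0
_PTV_LOG_SD = 0.5
#: share of latent plan-intensity variance explained by (log) PTV size
_PTV_LATENT_WEIGHT = 0.5


def _shape(x: float | np.ndarray):
    """(1 - exp(-x)) / x with the x -> 0 limit of 1."""
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = np.abs(x) > 1e-12
    out[nz] = (1.0 - np.exp(-x[nz])) / x[nz]
    return out if out.ndim else float(out)


#: smallest admissible plateau fraction (plateau at 2 % of baseline)
_F_MIN = 0.02


def _inv_shape(s_target: float) -> float:
    """Invert ``_shape`` on x > 0 (strictly decreasing) by bisection."""
    lo, hi = 1e-9, 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _shape(mid) > s_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the cohort summaries the analysis is calibrated
    against: median baseline ALC 2.07 (10^3/uL), median percentage ALC
    loss ~52 % (higher under concurrent chemoradiotherapy), median nadir
    ~0.54, and a dominant first principal component (~50 % of DVH metric
    variance) induced by a single latent plan-intensity factor.
    """

    n_patients: int = 306
    frac_crt: float = 0.37
    frac_vmat: float = 0.59
    baseline_alc_median: float = 2.07       # 10^3/uL
    baseline_alc_log_sd: float = 0.35
    decay_rate_base: float = 0.10           # per day
    decay_rate_log_sd: float = 0.30
    plateau_fraction_base: float = 0.36     # fraction of baseline
    effect_crt_on_loss: float = 7.0         # percentage points
    effect_dose_factor_on_loss: float = 8.0  # pp per unit latent factor
    loss_noise_sd: float = 9.0              # pp, patient-level
    alc_noise_sd: float = 0.16              # 10^3/uL, measurement-level
    visit_interval_days: int = 7
    visit_jitter_days: int = 2
    fit_window: float = 45.0                # days
    frac_pathological: float = 0.08
    dvh_noise_scale: float = 1.0            # multiplies per-metric noise sds
    dvh_ar_rho: float = 0.8                 # noise correlation along Vx grid
    dvh_loadings: Mapping[str, Mapping[str, float]] | None = None
    technique_effects: Mapping[str, float] | None = None  # "structure:metric" -> shift for VMAT
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_patients) < 1:
            raise ConfigurationError("n_patients must be >= 1")
        for name in ("frac_crt", "frac_vmat", "frac_pathological"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        for name in ("baseline_alc_median", "decay_rate_base", "fit_window",
                     "visit_interval_days"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("baseline_alc_log_sd", "decay_rate_log_sd",
                     "loss_noise_sd", "alc_noise_sd", "dvh_noise_scale",
                     "visit_jitter_days"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.plateau_fraction_base < 1.0:
            raise ConfigurationError("plateau_fraction_base must lie in [0, 1)")
        if not -1.0 < self.dvh_ar_rho < 1.0:
            raise ConfigurationError("dvh_ar_rho must lie in (-1, 1)")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        data = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration field(s): {', '.join(sorted(unknown))}")
        return cls(**data)


@dataclass(frozen=True)
class PatientTruth:
    """Ground-truth state of one simulated patient."""

    patient_id: str
    true_a: float          # 10^3/uL
    true_b: float          # per day
    true_c: float          # 10^3/uL
    latent_dose_factor: float
    true_percent_loss: float
    pathology: str
    crt: bool
    technique: str         # IMRT | VMAT
    baseline_alc: float
    ptv_cm3: float
    n_fractions: int
    total_dose_gy: float


@dataclass(frozen=True)
class Cohort:
    """Generated cohort tables (all pandas DataFrames)."""

    truth: pd.DataFrame
    blood: pd.DataFrame
    clinical: pd.DataFrame
    dvh: pd.DataFrame
    config: CohortConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("truth", self.truth), ("blood", self.blood),
                         ("clinical", self.clinical), ("dvh", self.dvh)):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths

    def series(self) -> dict[str, BloodCountSeries]:
        out = {}
        for pid, grp in self.blood.groupby("patient_id", sort=True):
            out[str(pid)] = BloodCountSeries(
                str(pid), grp["day"].to_numpy(float), grp["alc"].to_numpy(float))
        return out


# ---------------------------------------------------------------------------
# DVH latent-factor model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StructureDVHModel:
    """Mean profile, latent-factor loadings and noise model for the
    metrics of one structure (order: Dmin, Dmean, Dmax, then the Vx
    grid)."""

    structure: str
    means: np.ndarray
    loadings: np.ndarray
    noise_sd: np.ndarray
    ar_rho: float

    def noise_cov(self) -> np.ndarray:
        """Noise covariance: independent dose metrics, AR(1)-correlated
        volume metrics along the threshold grid."""
        m = len(ALL_METRICS)
        nv = len(V_LABELS)
        cov = np.zeros((m, m))
        nd = len(D_METRICS)
        for i in range(nd):
            cov[i, i] = self.noise_sd[i] ** 2
        idx = np.arange(nv)
        ar = self.ar_rho ** np.abs(idx[:, None] - idx[None, :])
        sv = self.noise_sd[nd:]
        cov[nd:, nd:] = np.outer(sv, sv) * ar
        return cov


#: per-structure cDVH shape: V(x) = A * exp(-x / tau), plus dose summaries
_PROFILES: dict[str, dict[str, float]] = {
    "lungs_sum": dict(A=90.0, tau=16.0, d_min=0.3, d_mean=14.0, d_max=62.0),
    "heart":     dict(A=80.0, tau=13.0, d_min=0.2, d_mean=10.0, d_max=55.0),
    "body":      dict(A=45.0, tau=9.0,  d_min=0.1, d_mean=6.0,  d_max=64.0),
}

_LOADING_SCALE = 0.2
#: noise-to-loading ratio rises along the Vx grid, so high-dose tail
#: metrics carry proportionally more plan-specific noise
_NOISE_FACTOR_V0 = 0.85
_NOISE_FACTOR_STEP = 0.045
_NOISE_FACTOR_D = 1.1


def default_dvh_model(
    config: CohortConfig | None = None,
) -> dict[str, StructureDVHModel]:
    """Build the default latent-factor DVH model, honouring any loading
    overrides and the noise scale in the configuration."""
    overrides = (config.dvh_loadings or {}) if config else {}
    noise_scale = config.dvh_noise_scale if config else 1.0
    ar_rho = config.dvh_ar_rho if config else 0.8
    models = {}
    for struct in STRUCTURES:
        prof = _PROFILES[struct]
        means = np.empty(len(ALL_METRICS))
        loadings = np.empty(len(ALL_METRICS))
        noise = np.empty(len(ALL_METRICS))
        for j, m in enumerate(D_METRICS):
            mu = prof[{"Dmin": "d_min", "Dmean": "d_mean", "Dmax": "d_max"}[m]]
            means[j] = mu
            loadings[j] = _LOADING_SCALE * mu
            noise[j] = _NOISE_FACTOR_D * loadings[j]
        nd = len(D_METRICS)
        for i, x in enumerate(DVH_GRID):
            mu = prof["A"] * math.exp(-x / prof["tau"])
            lam = min(_LOADING_SCALE * mu, (100.0 - mu) / 3.5)
            means[nd + i] = mu
            loadings[nd + i] = lam
            noise[nd + i] = (_NOISE_FACTOR_V0 + _NOISE_FACTOR_STEP * i) * lam
        over = overrides.get(struct, {})
        for j, m in enumerate(ALL_METRICS):
            if m in over:
                loadings[j] = float(over[m])
        noise *= noise_scale
        models[struct] = StructureDVHModel(struct, means, loadings, noise,
                                           ar_rho)
    return models


def _pava_decreasing(y: np.ndarray) -> np.ndarray:
    """Project a sequence onto non-increasing order (pool adjacent
    violators, unweighted L2)."""
    vals: list[float] = []
    counts: list[int] = []
    for v in y:
        vals.append(float(v))
        counts.append(1)
        while len(vals) > 1 and vals[-2] < vals[-1]:
            v2, c2 = vals.pop(), counts.pop()
            v1, c1 = vals.pop(), counts.pop()
            vals.append((v1 * c1 + v2 * c2) / (c1 + c2))
            counts.append(c1 + c2)
    return np.repeat(vals, counts)


def generate_dvh(
    truth: PatientTruth,
    rng: np.random.Generator,
    model: Mapping[str, StructureDVHModel] | None = None,
    technique_effects: Mapping[str, float] | None = None,
) -> list[DVHRecord]:
    """Sample the lungs/heart/body cDVH records of one patient.

    Violations of cDVH validity introduced by the additive noise (volumes
    outside [0, 100], non-monotone Vx, mean outside [min, max]) are
    repaired before emitting, so every record passes ``validate_cdvh``.
    """
    models = model if model is not None else default_dvh_model()
    effects = technique_effects or {}
    records = []
    nd = len(D_METRICS)
    for struct in STRUCTURES:
        sm = models[struct]
        chol = _noise_chol(sm)
        w = rng.standard_normal(len(ALL_METRICS))
        vals = sm.means + sm.loadings * truth.latent_dose_factor + chol @ w
        if truth.technique == "VMAT":
            for j, m in enumerate(ALL_METRICS):
                key = f"{struct}:{m}"
                if key in effects:
                    vals[j] += effects[key]
        d_min, d_mean, d_max = vals[:nd]
        d_min = max(d_min, 0.0)
        d_max = max(d_max, d_min)
        d_mean = min(max(d_mean, d_min), d_max)
        v = np.clip(vals[nd:], 0.0, 100.0)
        if np.any(np.diff(v) > 0):
            v = np.clip(_pava_decreasing(v), 0.0, 100.0)
        vx = {float(x): float(val) for x, val in zip(DVH_GRID, v)}
        records.append(DVHRecord(truth.patient_id, struct, float(d_min),
                                 float(d_max), float(d_mean), vx))
    return records


def _noise_chol(model: StructureDVHModel) -> np.ndarray:
    if not np.any(model.noise_sd > 0):
        return np.zeros((len(ALL_METRICS), len(ALL_METRICS)))
    return np.linalg.cholesky(model.noise_cov()
                              + 1e-12 * np.eye(len(ALL_METRICS)))


def _precomputed_chols(models: Mapping[str, StructureDVHModel]):
    return {s: _noise_chol(m) for s, m in models.items()}


def population_metric_covariance(
    config: CohortConfig | None = None,
) -> tuple[list[str], np.ndarray]:
    """Population covariance of the 51 DVH metrics implied by the
    configured latent-factor model (before clipping and monotonicity
    repair, which perturb it only slightly at default noise levels)."""
    cfg = config or CohortConfig()
    models = default_dvh_model(cfg)
    lam = np.concatenate([models[s].loadings for s in STRUCTURES])
    names = [f"{s}_{m}" for s in STRUCTURES for m in ALL_METRICS]
    p = lam.size
    cov = np.outer(lam, lam)
    k = len(ALL_METRICS)
    for si, s in enumerate(STRUCTURES):
        sl = slice(si * k, (si + 1) * k)
        cov[sl, sl] += models[s].noise_cov()
    return names, cov


def population_pc1_fraction(config: CohortConfig | None = None) -> float:
    """Fraction of variance the first principal component of the
    standardized metric matrix explains, from the population covariance."""
    _, cov = population_metric_covariance(config)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    eigvals = np.linalg.eigvalsh(corr)
    return float(eigvals[-1] / eigvals.sum())


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _visit_days(rng: np.random.Generator, config: CohortConfig) -> np.ndarray:
    """Baseline day (0 to 5 days before RT start) plus jittered weekly
    visits inside the fit window."""
    baseline_day = -int(rng.integers(0, 6))
    n_weeks = math.ceil(config.fit_window / config.visit_interval_days)
    days = [baseline_day]
    j = config.visit_jitter_days
    for k in range(1, n_weeks + 1):
        d = k * config.visit_interval_days + int(rng.integers(-j, j + 1))
        days.append(int(np.clip(d, 1, config.fit_window)))
    return np.unique(np.asarray(days, dtype=float))


def _sparse_visit_days(rng: np.random.Generator,
                       config: CohortConfig) -> np.ndarray:
    """Only two counts inside the window (plus one after it): exercises
    the insufficient-points failure while satisfying the three-test
    inclusion rule."""
    baseline_day = -int(rng.integers(0, 6))
    mid = 21 + int(rng.integers(-config.visit_jitter_days,
                                config.visit_jitter_days + 1))
    late = config.fit_window + 7 + int(rng.integers(0, 7))
    return np.unique(np.asarray([baseline_day, mid, late], dtype=float))


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw a full synthetic cohort; deterministic given the config seed."""
    cfg = config or CohortConfig()
    n = int(cfg.n_patients)
    rng = np.random.default_rng(cfg.seed)
    T = cfg.fit_window

    crt = rng.random(n) < cfg.frac_crt
    technique = np.where(rng.random(n) < cfg.frac_vmat, "VMAT", "IMRT")
    baseline = cfg.baseline_alc_median * np.exp(
        cfg.baseline_alc_log_sd * rng.standard_normal(n))
    z_ptv = rng.standard_normal(n)
    ptv = _PTV_MEDIAN_CM3 * np.exp(_PTV_LOG_SD * z_ptv)
    latent = (_PTV_LATENT_WEIGHT * z_ptv
              + math.sqrt(1.0 - _PTV_LATENT_WEIGHT**2)
              * rng.standard_normal(n))
    b = np.clip(cfg.decay_rate_base
                * np.exp(cfg.decay_rate_log_sd * rng.standard_normal(n)),
                0.0, 1.0)
    loss_noise = rng.normal(0.0, cfg.loss_noise_sd, n)
    age = np.clip(rng.normal(67.0, 8.0, n), 35.0, 90.0).round(1)
    sex = rng.choice(["M", "F"], size=n, p=[0.65, 0.35])
    rx_idx = rng.choice(len(_PRESCRIPTIONS), size=n, p=_PRESCRIPTION_P)
    total_dose = np.array([_PRESCRIPTIONS[i][0] for i in rx_idx])
    n_fractions = np.array([_PRESCRIPTIONS[i][1] for i in rx_idx])

    pathology = np.full(n, PATHOLOGY_NONE, dtype=object)
    n_path = int(round(cfg.frac_pathological * n))
    if n_path:
        path_idx = rng.choice(n, size=n_path, replace=False)
        kinds = [PATHOLOGY_RISING, PATHOLOGY_FLAT, PATHOLOGY_SPARSE]
        for k, i in enumerate(path_idx):
            pathology[i] = kinds[k % 3]

    # target loss (pp) linear in covariates; plateau solved per patient so
    # the closed-form loss matches the target exactly
    loss_base = 100.0 * (1.0 - cfg.plateau_fraction_base) \
        * (1.0 - _shape(cfg.decay_rate_base * T))
    loss_target = (loss_base
                   + cfg.effect_crt_on_loss * crt
                   + cfg.effect_dose_factor_on_loss * latent
                   + loss_noise)
    # a slow decay caps the attainable loss at 100*(1-shape(b*T)); when a
    # patient's target exceeds that ceiling, speed up their depletion rate
    # (intense plans deplete faster) rather than clip, so the configured
    # covariate effects stay exactly linear
    f_raw = 1.0 - loss_target / (100.0 * (1.0 - _shape(b * T)))
    for i in np.where(f_raw < _F_MIN)[0]:
        s_t = 1.0 - loss_target[i] / (100.0 * (1.0 - _F_MIN))
        if s_t <= _shape(1.0 * T):  # unattainable even at b = 1/day
            b[i] = 1.0
        else:
            b[i] = _inv_shape(s_t) / T
    frac = np.clip(1.0 - loss_target / (100.0 * (1.0 - _shape(b * T))),
                   _F_MIN, 0.98)
    true_c = frac * baseline
    true_a = baseline - true_c

    models = default_dvh_model(cfg)
    chols = _precomputed_chols(models)
    effects = cfg.technique_effects or {}
    nd = len(D_METRICS)

    width = len(str(n))
    truth_rows = []
    blood_rows = []
    clinical_rows = []
    dvh_records: list[DVHRecord] = []

    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        path = pathology[i]
        if path == PATHOLOGY_FLAT:
            a_i, b_i, c_i = 0.0, 0.0, float(baseline[i])
            loss_i = 0.0
        elif path == PATHOLOGY_RISING:
            a_i = b_i = c_i = loss_i = float("nan")
        else:
            a_i, b_i, c_i = float(true_a[i]), float(b[i]), float(true_c[i])
            loss_i = percent_alc_loss(a_i, b_i, c_i, float(baseline[i]), T)

        truth = PatientTruth(
            patient_id=pid, true_a=a_i, true_b=b_i, true_c=c_i,
            latent_dose_factor=float(latent[i]),
            true_percent_loss=loss_i, pathology=str(path), crt=bool(crt[i]),
            technique=str(technique[i]), baseline_alc=float(baseline[i]),
            ptv_cm3=float(ptv[i]), n_fractions=int(n_fractions[i]),
            total_dose_gy=float(total_dose[i]))
        truth_rows.append(truth)

        # blood-count series
        if path == PATHOLOGY_SPARSE:
            days = _sparse_visit_days(rng, cfg)
        else:
            days = _visit_days(rng, cfg)
        t_eval = np.maximum(days, 0.0)
        if path == PATHOLOGY_RISING:
            curve = baseline[i] * (1.0 + 0.012 * t_eval)
            noise_sd = cfg.alc_noise_sd
        elif path == PATHOLOGY_FLAT:
            curve = np.full_like(t_eval, baseline[i])
            noise_sd = max(0.5, cfg.alc_noise_sd) if cfg.alc_noise_sd > 0 \
                else 0.0
        else:
            curve = a_i * np.exp(-b_i * t_eval) + c_i
            noise_sd = cfg.alc_noise_sd
        alc_obs = np.clip(curve + rng.normal(0.0, noise_sd or 0.0,
                                             days.size)
                          if noise_sd > 0 else curve, 0.0, None)
        anc0 = 4.5 * math.exp(0.25 * rng.standard_normal())
        anc_curve = anc0 * (1.0 - 0.35 * crt[i]
                            * np.minimum(t_eval, 30.0) / 30.0)
        anc_obs = np.clip(anc_curve
                          + (rng.normal(0.0, 0.3, days.size)
                             if cfg.alc_noise_sd > 0 else 0.0), 0.0, None)
        for d, alc_v, anc_v in zip(days, alc_obs, anc_obs):
            blood_rows.append((pid, int(d), float(alc_v), float(anc_v)))

        clinical_rows.append((pid, float(age[i]), str(sex[i]),
                              str(technique[i]), bool(crt[i]),
                              float(total_dose[i]), int(n_fractions[i]),
                              float(ptv[i])))

        # DVH records (same latent model as generate_dvh, cholesky cached)
        for struct in STRUCTURES:
            sm = models[struct]
            w = rng.standard_normal(len(ALL_METRICS))
            vals = sm.means + sm.loadings * latent[i] + chols[struct] @ w
            if technique[i] == "VMAT":
                for j, m in enumerate(ALL_METRICS):
                    key = f"{struct}:{m}"
                    if key in effects:
                        vals[j] += effects[key]
            d_min, d_mean, d_max = vals[:nd]
            d_min = max(d_min, 0.0)
            d_max = max(d_max, d_min)
            d_mean = min(max(d_mean, d_min), d_max)
            v = np.clip(vals[nd:], 0.0, 100.0)
            if np.any(np.diff(v) > 0):
                v = np.clip(_pava_decreasing(v), 0.0, 100.0)
            vx = {float(x): float(val) for x, val in zip(DVH_GRID, v)}
            dvh_records.append(DVHRecord(pid, struct, float(d_min),
                                         float(d_max), float(d_mean), vx))

    truth_df = pd.DataFrame([asdict(t) for t in truth_rows])
    blood_df = pd.DataFrame(blood_rows,
                            columns=["patient_id", "day", "alc", "anc"])
    clinical_df = pd.DataFrame(
        clinical_rows,
        columns=["patient_id", "age", "sex", "technique", "crt",
                 "total_dose_gy", "n_fractions", "ptv_cm3"])
    dvh_df = dvh_long_from_records(dvh_records)
    return Cohort(truth_df, blood_df, clinical_df, dvh_df, cfg)
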