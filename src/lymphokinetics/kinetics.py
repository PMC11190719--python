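"""Per-patient lymphocyte-depletion kinetics.

Each patient's absolute lymphocyte count (ALC, 10^3/uL) during the first
weeks of radiotherapy is modelled as a bounded exponential decay

    ALC(t) = a * exp(-b * t) + c,      a >= 0, c >= 0,

with ``t`` in days from the first fraction.  ``a + c`` is the day-0 count,
``b`` the depletion rate (per day) and ``c`` the plateau the count settles
to while treatment continues.  The endpoint derived from the fit is the
percentage ALC loss relative to baseline, computed from the area under the
fitted curve over the observation window: a patient whose curve stays at
baseline loses 0 %, one whose curve drops instantly to zero loses 100 %.

Fits are quality-controlled: a depletion rate outside [0, 1]/day, an R^2
below 0.5, fewer than three usable points, or optimizer non-convergence
each yield a distinct failure status and exclude the patient from the
association analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import BaselineMissingError, DomainError

__all__ = [
    "BloodCountSeries",
    "DecayFit",
    "LymphoEndpoint",
    "select_baseline",
    "fit_decay",
    "auc_closed_form",
    "percent_alc_loss",
    "nadir",
    "ctcae_grade",
    "compute_endpoints",
    "STATUS_SUCCESS",
    "STATUS_FAIL_NO_CONVERGE",
    "STATUS_FAIL_B_RANGE",
    "STATUS_FAIL_R2",
    "STATUS_FAIL_INSUFFICIENT",
    "FIT_STATUSES",
]

STATUS_SUCCESS = "success"
STATUS_FAIL_NO_CONVERGE = "fail_no_converge"
STATUS_FAIL_B_RANGE = "fail_b_range"
STATUS_FAIL_R2 = "fail_r2"
STATUS_FAIL_INSUFFICIENT = "fail_insufficient_points"

FIT_STATUSES = (
    STATUS_SUCCESS,
    STATUS_FAIL_NO_CONVERGE,
    STATUS_FAIL_B_RANGE,
    STATUS_FAIL_R2,
    STATUS_FAIL_INSUFFICIENT,
)

#: QC bounds on the depletion rate (per day); fits outside fail.
B_RANGE = (0.0, 1.0)
#: numerical slack on the rate bounds, so a boundary optimum (e.g. a
#: perfect constant fit with b = -1e-11) is not misclassified
B_TOL = 1e-8
#: Minimum R^2 for a fit to count as successful.
R2_MIN = 0.5
#: Earliest day (relative to RT start) a count may serve as baseline.
BASELINE_EARLIEST_DAY = -91.0
#: Latest day a count may serve as baseline.
BASELINE_LATEST_DAY = 2.0


@dataclass(frozen=True)
class BloodCountSeries:
    """One patient's timestamped ALC measurements.

    ``times`` are days relative to the first RT fraction (pre-treatment
    counts are negative).  Same-day duplicates are averaged on
    construction so times are strictly increasing.
    """

    patient_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size < 1:
            raise ValueError("a blood-count series needs at least one measurement")
        if np.any(v < 0):
            raise ValueError("ALC values must be non-negative")
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        tu, inverse = np.unique(t, return_inverse=True)
        if tu.size != t.size:  # average same-day duplicates
            vu = np.bincount(inverse, weights=v) / np.bincount(inverse)
            t, v = tu, vu
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class DecayFit:
    """Result of fitting the exponential-decay model to one series."""

    a: float
    b: float
    c: float
    r_squared: float
    n_points: int
    window_end_T: float
    status: str

    @property
    def ok(self) -> bool:
        return self.status == STATUS_SUCCESS

    def predict(self, t):
        t = np.asarray(t, dtype=float)
        return self.a * np.exp(np.clip(-self.b * t, -50.0, 50.0)) + self.c


@dataclass(frozen=True)
class LymphoEndpoint:
    """Derived endpoint values for one patient."""

    baseline_alc: float
    auc: float
    fit_time_T: float
    percent_loss: float
    nadir: float
    ctcae_grade: int
    severe_ril: bool
    negative_loss_flag: bool = field(default=False)


def select_baseline(
    series: BloodCountSeries,
    *,
    latest_day: float = BASELINE_LATEST_DAY,
    earliest_day: float = BASELINE_EARLIEST_DAY,
) -> tuple[float, float]:
    """Pick the baseline ALC: the measurement closest to RT start.

    Eligible counts lie in ``[earliest_day, latest_day]`` (by default at
    most 91 days before and at most 2 days after the first fraction).
    Ties in distance to day 0 are broken toward the later measurement.

    Returns ``(baseline_alc, baseline_time)``; raises
    :class:`BaselineMissingError` when no count is eligible.
    """
    t, v = series.times, series.values
    eligible = (t >= earliest_day) & (t <= latest_day)
    if not np.any(eligible):
        raise BaselineMissingError(
            f"patient {series.patient_id}: no ALC between day "
            f"{earliest_day:g} and day {latest_day:g}"
        )
    te, ve = t[eligible], v[eligible]
    # closest to day 0; on a tie prefer the later (larger t) measurement
    order = np.lexsort((-te, np.abs(te)))
    i = order[0]
    return float(ve[i]), float(te[i])


def _assemble_fit_points(
    series: BloodCountSeries,
    baseline: tuple[float, float],
    window: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Points used for fitting: the baseline mapped to t = 0 when it was
    taken before RT start, plus every measurement in [0, window]."""
    bl_val, bl_t = baseline
    t, v = series.times, series.values
    mask = (t >= 0.0) & (t <= window)
    ts = list(t[mask])
    vs = list(v[mask])
    if bl_t < 0.0:
        ts.append(0.0)
        vs.append(bl_val)
    ts = np.asarray(ts, dtype=float)
    vs = np.asarray(vs, dtype=float)
    order = np.argsort(ts, kind="stable")
    ts, vs = ts[order], vs[order]
    tu, inverse = np.unique(ts, return_inverse=True)
    if tu.size != ts.size:
        vs = np.bincount(inverse, weights=vs) / np.bincount(inverse)
        ts = tu
    return ts, vs


def _r_squared(y: np.ndarray, resid: np.ndarray) -> float:
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < 1e-12:
        # constant observations: a perfect constant fit gets R^2 = 1
        return 1.0 if ss_res < 1e-8 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_decay(
    series: BloodCountSeries,
    baseline: tuple[float, float] | None = None,
    *,
    window: float = 45.0,
    init_rate: float = 0.10,
    init_plateau: float = 0.34,
    max_nfev: int = 1000,
) -> DecayFit:
    """Fit ``a*exp(-b*t) + c`` to one patient's in-window counts.

    ``a`` and ``c`` are constrained non-negative; ``b`` is left free
    during optimization and range-checked afterwards, so that too-fast or
    rising kinetics surface as QC failures rather than boundary fits.
    Initial values follow literature-scale kinetics: depletion rate 0.10
    per day and plateau 0.34 (10^3/uL).

    Never raises for a fit problem: non-convergence, out-of-range rate,
    low R^2 and too few points are all reported through ``status``.
    """
    if baseline is None:
        baseline = select_baseline(series)
    bl_val, _ = baseline
    ts, vs = _assemble_fit_points(series, baseline, window)
    n = int(ts.size)
    t_last = float(ts.max()) if n else float("nan")
    if n < 3:
        return DecayFit(np.nan, np.nan, np.nan, np.nan, n, t_last,
                        STATUS_FAIL_INSUFFICIENT)

    def model(p, t):
        a, b, c = p
        return a * np.exp(np.clip(-b * t, -50.0, 50.0)) + c

    def resid(p):
        return model(p, ts) - vs

    def jac(p):
        a, b, _ = p
        e = np.exp(np.clip(-b * ts, -50.0, 50.0))
        return np.column_stack([e, -a * ts * e, np.ones_like(ts)])

    x0 = np.array([max(bl_val - init_plateau, 0.01), init_rate, init_plateau])
    res = least_squares(
        resid,
        x0,
        jac=jac,
        bounds=([0.0, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
        method="trf",
        xtol=1e-10,
        ftol=1e-10,
        gtol=1e-10,
        max_nfev=max_nfev,
    )
    a, b, c = (float(x) for x in res.x)
    r2 = _r_squared(vs, resid(res.x))
    if res.status == 0:  # hit max_nfev without meeting a tolerance
        status = STATUS_FAIL_NO_CONVERGE
    elif b < B_RANGE[0] - B_TOL or b > B_RANGE[1] + B_TOL:
        status = STATUS_FAIL_B_RANGE
    elif r2 < R2_MIN:
        status = STATUS_FAIL_R2
    else:
        status = STATUS_SUCCESS
    return DecayFit(a, b, c, r2, n, t_last, status)


def auc_closed_form(a: float, b: float, c: float, T: float) -> float:
    """Area under ``a*exp(-b*t) + c`` over [0, T].

    Equals ``a/b * (1 - exp(-b*T)) + c*T``, with the ``b -> 0`` limit
    ``(a + c) * T``.  ``T`` must be positive.
    """
    if T <= 0:
        raise DomainError(f"integration time T must be positive, got {T!r}")
    if abs(b) < 1e-12:
        return (a + c) * T
    return a / b * (1.0 - np.exp(-b * T)) + c * T


def percent_alc_loss(
    a: float, b: float, c: float, baseline_alc: float, T: float
) -> float:
    """Percentage ALC loss relative to baseline over [0, T].

    ``100 * (1 - AUC(0..T) / (baseline_alc * T))``: the lost fraction of
    the rectangle a constant-at-baseline count would cover.  May be
    negative when the fitted curve exceeds baseline; callers flag rather
    than clamp such values.
    """
    if baseline_alc <= 0:
        raise DomainError(f"baseline ALC must be positive, got {baseline_alc!r}")
    return 100.0 * (1.0 - auc_closed_form(a, b, c, T) / (baseline_alc * T))


def nadir(series: BloodCountSeries, window: float = 45.0) -> float:
    """Lowest measured ALC in [0, window] days."""
    mask = (series.times >= 0.0) & (series.times <= window)
    if not np.any(mask):
        raise DomainError(
            f"patient {series.patient_id}: no measurement in [0, {window:g}] days"
        )
    return float(series.values[mask].min())


def ctcae_grade(nadir_value: float, *, lln: float = 1.0) -> int:
    """CTCAE lymphopenia grade from the nadir ALC (10^3/uL).

    Grade 4 below 0.2, grade 3 below 0.5, grade 2 below 0.8, grade 1
    below the lower limit of normal (default 1.0), else 0.  Grade >= 3
    defines severe radiation-induced lymphopenia.
    """
    if nadir_value < 0:
        raise DomainError(f"nadir must be non-negative, got {nadir_value!r}")
    if nadir_value < 0.2:
        return 4
    if nadir_value < 0.5:
        return 3
    if nadir_value < 0.8:
        return 2
    if nadir_value < lln:
        return 1
    return 0


ENDPOINT_COLUMNS = [
    "patient_id", "baseline_alc", "a", "b", "c", "r_squared", "n_points",
    "status", "auc", "fit_time_T", "percent_loss", "negative_loss_flag",
    "nadir", "ctcae_grade", "severe_ril",
]


def compute_endpoints(
    series_iter: Iterable[BloodCountSeries] | Mapping[str, BloodCountSeries],
    *,
    window: float = 45.0,
    init_rate: float = 0.10,
    init_plateau: float = 0.34,
    lln: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run baseline selection, decay fitting and endpoint derivation.

    Returns ``(endpoints, exclusions)``.  ``endpoints`` has one row per
    patient with an eligible baseline (successful or failed fit alike);
    ``exclusions`` lists patients that could not enter fitting at all,
    with a reason.
    """
    if isinstance(series_iter, Mapping):
        series_iter = series_iter.values()
    rows = []
    excluded = []
    for series in series_iter:
        try:
            bl_val, bl_t = select_baseline(series)
        except BaselineMissingError as exc:
            excluded.append({"patient_id": series.patient_id,
                             "reason": str(exc)})
            continue
        fit = fit_decay(series, (bl_val, bl_t), window=window,
                        init_rate=init_rate, init_plateau=init_plateau)
        try:
            nad = nadir(series, window)
        except DomainError:
            nad = np.nan
        grade = ctcae_grade(nad, lln=lln) if np.isfinite(nad) else np.nan
        if fit.ok:
            auc = auc_closed_form(fit.a, fit.b, fit.c, fit.window_end_T)
            loss = percent_alc_loss(fit.a, fit.b, fit.c, bl_val,
                                    fit.window_end_T)
        else:
            auc = np.nan
            loss = np.nan
        rows.append({
            "patient_id": series.patient_id,
            "baseline_alc": bl_val,
            "a": fit.a, "b": fit.b, "c": fit.c,
            "r_squared": fit.r_squared,
            "n_points": fit.n_points,
            "status": fit.status,
            "auc": auc,
            "fit_time_T": fit.window_end_T,
            "percent_loss": loss,
            "negative_loss_flag": bool(np.isfinite(loss) and loss < 0),
            "nadir": nad,
            "ctcae_grade": grade,
            "severe_ril": bool(np.isfinite(nad) and nad < 0.5),
        })
    endpoints = pd.DataFrame(rows, columns=ENDPOINT_COLUMNS)
    exclusions = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return endpoints, exclusions
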