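"""CSV readers and writers for the pipeline's table schemas.

All tables are plain CSV.  Blood counts arrive long-format (one row per
measurement); days are integers relative to the first RT fraction, or
calendar dates resolved against a per-patient RT start date.  ALC is in
10^3/uL (equivalently 10^9/L): a file whose median ALC exceeds 20 was
almost certainly recorded in cells/uL and triggers a unit warning.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .dosimetry import ALL_METRICS, STRUCTURES
from .errors import SchemaError
from .kinetics import BloodCountSeries

__all__ = [
    "read_blood_csv",
    "read_clinical_csv",
    "read_dvh_csv",
    "MIN_MEASUREMENTS",
]

log = logging.getLogger("lymphokinetics")

#: inclusion rule: at least this many blood tests per patient
MIN_MEASUREMENTS = 3


def _require_columns(df: pd.DataFrame, required: set[str], path) -> None:
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s): "
            + ", ".join(sorted(missing)))


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna() & df[col].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise SchemaError(
            f"{path}: unparseable value in column '{col}' at line {line}")
    return out


def read_blood_csv(
    path: str | Path,
    rt_start: Mapping[str, str] | None = None,
    *,
    min_measurements: int = MIN_MEASUREMENTS,
) -> tuple[dict[str, BloodCountSeries], pd.DataFrame]:
    """Read the blood-count table into per-patient series.

    Requires ``patient_id``, ``alc`` and either a ``day`` column (days
    from RT start) or a ``date`` column together with an ``rt_start``
    mapping patient id -> RT start date.  Patients with fewer than three
    measurements are excluded with a reason (they cannot satisfy the
    decay-fit inclusion rule).

    Returns ``(series_by_patient, exclusions)``.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, {"patient_id", "alc"}, path)
    if "day" in df.columns:
        days = _numeric(df, "day", path)
    elif "date" in df.columns:
        if rt_start is None:
            raise SchemaError(
                f"{path}: has a 'date' column but no RT start dates were "
                "provided to anchor day 0")
        dates = pd.to_datetime(df["date"], errors="coerce")
        if dates.isna().any():
            line = int(dates.isna().idxmax()) + 2
            raise SchemaError(f"{path}: unparseable date at line {line}")
        starts = df["patient_id"].map(
            {k: pd.Timestamp(v) for k, v in rt_start.items()})
        if starts.isna().any():
            pid = df.loc[starts.isna(), "patient_id"].iloc[0]
            raise SchemaError(f"{path}: no RT start date for patient {pid}")
        days = (dates - starts).dt.days.astype(float)
    else:
        raise SchemaError(f"{path}: missing required column(s): day (or date)")
    alc = _numeric(df, "alc", path)
    if alc.median() > 20:
        log.warning("%s: median ALC %.1f suggests cells/uL rather than "
                    "10^3/uL; check units", path, alc.median())
    series: dict[str, BloodCountSeries] = {}
    excluded = []
    work = pd.DataFrame({"patient_id": df["patient_id"], "day": days,
                         "alc": alc})
    for pid, grp in work.groupby("patient_id", sort=True):
        if len(grp) < min_measurements:
            excluded.append({
                "patient_id": pid,
                "reason": f"fewer than {min_measurements} counts"})
            continue
        series[str(pid)] = BloodCountSeries(
            str(pid), grp["day"].to_numpy(float), grp["alc"].to_numpy(float))
    exclusions = pd.DataFrame(excluded, columns=["patient_id", "reason"])
    return series, exclusions


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    """Read the per-patient clinical table."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str})
    _require_columns(df, {"patient_id", "technique", "crt", "total_dose_gy",
                          "n_fractions", "ptv_cm3"}, path)
    for col in ("total_dose_gy", "n_fractions", "ptv_cm3"):
        df[col] = _numeric(df, col, path)
    if df["crt"].dtype == object:
        df["crt"] = df["crt"].astype(str).str.lower().isin(
            ("true", "1", "yes", "y"))
    df["crt"] = df["crt"].astype(bool)
    return df


def read_dvh_csv(path: str | Path) -> pd.DataFrame:
    """Read the long-format DVH table, checking structure and metric
    vocabulary."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"patient_id": str, "structure": str,
                                  "metric": str})
    _require_columns(df, {"patient_id", "structure", "metric", "value"}, path)
    df["value"] = _numeric(df, "value", path)
    bad_struct = set(df["structure"]) - set(STRUCTURES)
    if bad_struct:
        raise SchemaError(
            f"{path}: unknown structure(s): {', '.join(sorted(bad_struct))}")
    bad_metric = set(df["metric"]) - set(ALL_METRICS)
    if bad_metric:
        raise SchemaError(
            f"{path}: unknown metric(s): {', '.join(sorted(bad_metric))}")
    return df
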