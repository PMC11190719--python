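"""Dose-volume summaries, EQD2 conversion and EDRIC.

Works on cumulative DVH (cDVH) summaries per structure: minimum, mean and
maximum dose plus the Vx grid — the percentage of the structure's volume
receiving at least x Gy for x in {0.5, 1, 2, 5, 10, ..., 55}.  The three
structures tracked for lymphopenia risk are the sum of both lungs, the
heart and the whole body.

EQD2 re-expresses a dose D delivered in n fractions as the equivalent
dose in 2-Gy fractions under the linear-quadratic model,

    EQD2 = D * (d + alpha/beta) / (2 + alpha/beta),   d = D / n,

with alpha/beta = 10 Gy for all conversions.  EDRIC (effective dose of
radiation to circulating immune cells) combines mean lung, heart and body
dose with the fraction number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationFailure

__all__ = [
    "DVH_GRID",
    "STRUCTURES",
    "DVHRecord",
    "PlanSummary",
    "v_label",
    "validate_cdvh",
    "eqd2",
    "eqd2_transform_dvh",
    "edric",
    "plan_summary",
    "dvh_records_from_long",
    "dvh_long_from_records",
    "dvh_wide",
    "eqd2_transform_table",
    "edric_table",
]

#: Dose thresholds (Gy) of the cumulative-DVH volume grid.
DVH_GRID: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0, 10.0, 15.0, 20.0, 25.0,
                               30.0, 35.0, 40.0, 45.0, 50.0, 55.0)

STRUCTURES: tuple[str, ...] = ("lungs_sum", "heart", "body")

D_METRICS: tuple[str, ...] = ("Dmin", "Dmean", "Dmax")


def v_label(threshold: float) -> str:
    """Column label for a Vx threshold: 0.5 -> 'V0.5', 20.0 -> 'V20'."""
    return f"V{threshold:g}"


V_LABELS: tuple[str, ...] = tuple(v_label(x) for x in DVH_GRID)
ALL_METRICS: tuple[str, ...] = D_METRICS + V_LABELS


@dataclass(frozen=True)
class DVHRecord:
    """Cumulative DVH summary of one structure for one patient."""

    patient_id: str
    structure: str
    d_min: float
    d_max: float
    d_mean: float
    vx: Mapping[float, float]  # threshold (Gy) -> volume (%)

    def vx_array(self, grid: Sequence[float] = DVH_GRID) -> np.ndarray:
        return np.array([self.vx[x] for x in grid], dtype=float)


@dataclass(frozen=True)
class PlanSummary:
    """Mean doses to the immune-relevant structures plus EDRIC."""

    mld: float
    mhd: float
    mbd: float
    n_fractions: int
    edric: float


def validate_cdvh(record: DVHRecord) -> list[str]:
    """Structural checks on a cDVH record; returns named issues.

    An empty list means valid.  Never raises.
    """
    issues: list[str] = []
    for name, d in (("Dmin", record.d_min), ("Dmean", record.d_mean),
                    ("Dmax", record.d_max)):
        if d < 0:
            issues.append(f"negative {name}")
    if record.d_mean > record.d_max:
        issues.append("mean exceeds max")
    if record.d_min > record.d_mean:
        issues.append("min exceeds mean")
    thresholds = sorted(record.vx)
    prev = None
    prev_x = None
    for x in thresholds:
        v = record.vx[x]
        if not 0.0 <= v <= 100.0:
            issues.append(f"volume out of range at {x:g} Gy")
        if prev is not None and v > prev + 1e-9:
            issues.append(f"non-monotone Vx at {x:g} Gy")
        prev, prev_x = v, x
    return issues


def eqd2(total_dose: float, n_fractions: int, alpha_beta: float = 10.0) -> float:
    """Equivalent dose in 2-Gy fractions of ``total_dose`` given in
    ``n_fractions`` uniform fractions."""
    if n_fractions < 1:
        raise DomainError(f"n_fractions must be >= 1, got {n_fractions!r}")
    if total_dose < 0:
        raise DomainError(f"total dose must be >= 0, got {total_dose!r}")
    d = total_dose / n_fractions
    return total_dose * (d + alpha_beta) / (2.0 + alpha_beta)


def eqd2_transform_dvh(
    record: DVHRecord,
    n_fractions: int,
    alpha_beta: float = 10.0,
    grid: Sequence[float] = DVH_GRID,
) -> DVHRecord:
    """Re-express a cDVH on the EQD2 dose axis and resample the Vx grid.

    Every dose coordinate D (thresholds and Dmin/Dmean/Dmax) is mapped
    through ``eqd2`` with per-bin dose ``d = D / n_fractions``; the
    transform is strictly increasing in D, so the cumulative curve stays
    monotone.  Volumes are then linearly interpolated back onto the
    standard grid, carried flat at 100 % below the lowest transformed
    threshold and 0 % above the highest.
    """
    issues = validate_cdvh(record)
    if issues:
        raise ValidationFailure(
            f"patient {record.patient_id} {record.structure}: "
            + "; ".join(issues)
        )
    thresholds = np.array(sorted(record.vx), dtype=float)
    volumes = np.array([record.vx[x] for x in thresholds], dtype=float)
    mapped = np.array([eqd2(x, n_fractions, alpha_beta) for x in thresholds])
    new_vols = np.interp(np.asarray(grid, dtype=float), mapped, volumes,
                         left=100.0, right=0.0)
    new_vx = {float(x): float(v) for x, v in zip(grid, new_vols)}
    out = DVHRecord(
        patient_id=record.patient_id,
        structure=record.structure,
        d_min=eqd2(record.d_min, n_fractions, alpha_beta),
        d_max=eqd2(record.d_max, n_fractions, alpha_beta),
        d_mean=eqd2(record.d_mean, n_fractions, alpha_beta),
        vx=new_vx,
    )
    return out


def edric(
    mld: float,
    mhd: float,
    mbd: float,
    n_fractions: int,
    *,
    w_lung: float = 0.12,
    w_heart: float = 0.08,
    w_body_base: float = 0.45,
    w_body_slope: float = 0.35 * 0.85,
    n_ref: float = 45.0,
) -> float:
    """Effective dose of radiation to circulating immune cells (Gy).

    ``0.12*MLD + 0.08*MHD + (0.45 + 0.35*0.85*(n/45))*MBD`` with MLD/MHD/
    MBD the mean lung, heart and body doses and n the fraction number.
    The body term grows with n because each fraction re-irradiates the
    circulating blood pool.  The weights are exposed for sensitivity
    analyses.
    """
    if min(mld, mhd, mbd) < 0:
        raise DomainError("mean doses must be non-negative")
    if n_fractions < 1:
        raise DomainError(f"n_fractions must be >= 1, got {n_fractions!r}")
    return (w_lung * mld + w_heart * mhd
            + (w_body_base + w_body_slope * (n_fractions / n_ref)) * mbd)


def plan_summary(records: Sequence[DVHRecord], n_fractions: int) -> PlanSummary:
    """EDRIC summary from one patient's lungs/heart/body records."""
    by_struct = {r.structure: r for r in records}
    missing = [s for s in STRUCTURES if s not in by_struct]
    if missing:
        raise DomainError(f"missing DVH structures: {', '.join(missing)}")
    mld = by_struct["lungs_sum"].d_mean
    mhd = by_struct["heart"].d_mean
    mbd = by_struct["body"].d_mean
    return PlanSummary(mld, mhd, mbd, int(n_fractions),
                       edric(mld, mhd, mbd, n_fractions))


# ---------------------------------------------------------------------------
# Table-level helpers (long layout: patient_id, structure, metric, value)
# ---------------------------------------------------------------------------

def dvh_records_from_long(dvh_df: pd.DataFrame) -> list[DVHRecord]:
    """Build DVHRecord objects from the long-format DVH table."""
    records = []
    for (pid, struct), grp in dvh_df.groupby(["patient_id", "structure"],
                                             sort=True):
        metrics = dict(zip(grp["metric"], grp["value"].astype(float)))
        vx = {}
        for x in DVH_GRID:
            lab = v_label(x)
            if lab not in metrics:
                raise ValidationFailure(
                    f"patient {pid} {struct}: missing metric {lab}")
            vx[x] = metrics[lab]
        for m in D_METRICS:
            if m not in metrics:
                raise ValidationFailure(
                    f"patient {pid} {struct}: missing metric {m}")
        records.append(DVHRecord(str(pid), str(struct), metrics["Dmin"],
                                 metrics["Dmax"], metrics["Dmean"], vx))
    return records


def dvh_long_from_records(records: Sequence[DVHRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append((r.patient_id, r.structure, "Dmin", r.d_min))
        rows.append((r.patient_id, r.structure, "Dmean", r.d_mean))
        rows.append((r.patient_id, r.structure, "Dmax", r.d_max))
        for x in sorted(r.vx):
            rows.append((r.patient_id, r.structure, v_label(x), r.vx[x]))
    return pd.DataFrame(rows, columns=["patient_id", "structure", "metric",
                                       "value"])


def dvh_wide(dvh_df: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long DVH table to one row per patient with columns
    ``<structure>_<metric>`` (e.g. ``lungs_sum_V20``)."""
    wide = dvh_df.pivot_table(index="patient_id", columns=["structure", "metric"],
                              values="value", aggfunc="first")
    wide.columns = [f"{s}_{m}" for s, m in wide.columns]
    return wide.reset_index()


def eqd2_transform_table(
    dvh_df: pd.DataFrame,
    clinical_df: pd.DataFrame,
    alpha_beta: float = 10.0,
) -> pd.DataFrame:
    """EQD2-convert every patient/structure record in a long DVH table,
    using each patient's fraction number from the clinical table."""
    n_map = dict(zip(clinical_df["patient_id"].astype(str),
                     clinical_df["n_fractions"].astype(int)))
    records = dvh_records_from_long(dvh_df)
    out = []
    for r in records:
        if r.patient_id not in n_map:
            raise ValidationFailure(
                f"patient {r.patient_id}: no fraction number in clinical table")
        out.append(eqd2_transform_dvh(r, n_map[r.patient_id], alpha_beta))
    return dvh_long_from_records(out)


def edric_table(dvh_df: pd.DataFrame, clinical_df: pd.DataFrame) -> pd.DataFrame:
    """Per-patient MLD/MHD/MBD and EDRIC from a long DVH table.

    EDRIC is computed from physical (not EQD2-converted) mean doses.
    """
    n_map = dict(zip(clinical_df["patient_id"].astype(str),
                     clinical_df["n_fractions"].astype(int)))
    records = dvh_records_from_long(dvh_df)
    by_pid: dict[str, list[DVHRecord]] = {}
    for r in records:
        by_pid.setdefault(r.patient_id, []).append(r)
    rows = []
    for pid, recs in sorted(by_pid.items()):
        ps = plan_summary(recs, n_map[pid])
        rows.append({"patient_id": pid, "mld": ps.mld, "mhd": ps.mhd,
                     "mbd": ps.mbd, "n_fractions": ps.n_fractions,
                     "edric": ps.edric})
    return pd.DataFrame(rows)
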