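"""Umbrella pipeline: simulate -> endpoints -> dvh -> analyze -> report.

Each stage reads and writes CSV/JSON files in a run directory, so stages
can also be driven individually from the command line.  A stage writes
its outputs under a ``.partial`` suffix and renames them on success;
after a failure the partial files remain for inspection.  A manifest
records input hashes, the seed, package versions and per-stage counts,
which is sufficient to reproduce every output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (ModelReport, ancova_plan_comparison,
                       build_analysis_table, fit_multivariable, pca_dose,
                       spearman_endpoint_comparison, univariable_screen)
from .dosimetry import (dvh_records_from_long, dvh_wide, edric_table,
                        eqd2_transform_table, validate_cdvh)
from .errors import ValidationFailure
from .io import read_blood_csv, read_clinical_csv, read_dvh_csv
from .kinetics import compute_endpoints
from .synthetic import Cohort, CohortConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "analyze_tables", "render_report"]

log = logging.getLogger("lymphokinetics")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end run settings."""

    out_dir: Path
    seed: int = 0
    n_patients: int = 306
    window: float = 45.0
    eqd2: bool = True
    dose_summary: str = "pc1"            # highlighted model: pc1 | edric
    bootstrap_B: int = 300
    pca_include_ptv: bool = False
    cohort_config: CohortConfig | None = None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_write(path: Path, writer: Callable[[Path], None]) -> Path:
    """Write through a .partial file, renaming only on success."""
    tmp = path.with_name(path.name + ".partial")
    writer(tmp)
    tmp.replace(path)
    return path


def _write_json(obj, path: Path) -> None:
    def writer(p: Path):
        p.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
    _stage_write(path, writer)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    _stage_write(path, lambda p: df.to_csv(p, index=False))


def validate_dvh_table(dvh_df: pd.DataFrame) -> int:
    """Validate every record of a long DVH table; raises
    :class:`ValidationFailure` naming the first offending
    patient/structure."""
    records = dvh_records_from_long(dvh_df)
    for rec in records:
        issues = validate_cdvh(rec)
        if issues:
            raise ValidationFailure(
                f"invalid cDVH for patient {rec.patient_id} "
                f"({rec.structure}): " + "; ".join(issues))
    return len(records)


def _markdown_table(df: pd.DataFrame, float_fmt: str = "{:.3f}") -> str:
    def fmt(v):
        if isinstance(v, (float, np.floating)):
            return "" if not np.isfinite(v) else float_fmt.format(v)
        return str(v)
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = ["| " + " | ".join(fmt(v) for v in row) + " |"
            for row in df.itertuples(index=False)]
    return "\n".join([header, sep] + body)


def analyze_tables(
    endpoints: pd.DataFrame,
    clinical: pd.DataFrame,
    dvh_long: pd.DataFrame,
    *,
    bootstrap_B: int = 300,
    seed: int = 7,
    pca_include_ptv: bool = False,
) -> dict:
    """Run the full association analysis on in-memory tables.

    Returns a dict with the screen, ANCOVA, Spearman tables, the PCA
    result and both multivariable model reports (EDRIC and PC1).
    """
    edric = edric_table(dvh_long, clinical)
    wide = dvh_wide(dvh_long)
    table, metric_cols = build_analysis_table(endpoints, clinical, wide,
                                              edric)
    log.info("analysis table: %d complete-case patients, %d metrics",
             len(table), len(metric_cols))
    screen = univariable_screen(table, metric_cols)
    ancova = ancova_plan_comparison(table, metric_cols)
    spearman = spearman_endpoint_comparison(table, metric_cols)
    pca = pca_dose(table, metric_cols, include_ptv=pca_include_ptv)
    table = table.assign(pc1=pca.pc1_scores)
    model_edric = fit_multivariable(table, "edric", bootstrap_B=bootstrap_B,
                                    seed=seed)
    model_pc1 = fit_multivariable(table, "pc1", bootstrap_B=bootstrap_B,
                                  seed=seed)
    return {
        "table": table,
        "metric_cols": metric_cols,
        "screen": screen,
        "ancova": ancova,
        "spearman": spearman,
        "pca": pca,
        "model_edric": model_edric,
        "model_pc1": model_pc1,
    }


def _model_report_json(result: dict, seed: int) -> dict:
    return {
        "n": int(result["model_pc1"].n),
        "seed": seed,
        "model_1_edric": result["model_edric"].to_dict(),
        "model_2_pc1": result["model_pc1"].to_dict(),
    }


def render_report(result: dict, dose_summary: str = "pc1") -> str:
    """Render the analysis tables as a markdown report."""
    lines = ["# Lymphocyte-loss association report", ""]
    n = result["model_pc1"].n
    lines += [f"Complete-case patients analysed: {n}", ""]
    lines += ["## Univariable screen (top 15 by R^2)", ""]
    screen = result["screen"].dropna(subset=["r_squared"])
    top = screen.sort_values("r_squared", ascending=False).head(15)
    lines += [_markdown_table(top), ""]
    lines += ["## ANCOVA: VMAT vs IMRT adjusted for PTV (top 15 by |coef|)",
              ""]
    anc = result["ancova"].dropna(subset=["coef_vmat"])
    anc = anc.reindex(anc["coef_vmat"].abs()
                      .sort_values(ascending=False).index).head(15)
    lines += [_markdown_table(anc), ""]
    lines += ["## Spearman: metric vs percentage loss and nadir (top 15)", ""]
    spear = result["spearman"].dropna(subset=["rho_percent_loss"])
    spear = spear.reindex(spear["rho_percent_loss"].abs()
                          .sort_values(ascending=False).index).head(15)
    lines += [_markdown_table(spear), ""]
    pca = result["pca"]
    lines += ["## PCA of dose metrics", "",
              f"PC1 explains {100 * pca.pc1_explained:.1f} % of "
              "standardized metric variance.", ""]
    for key, title in (("model_edric", "Model 1 (EDRIC)"),
                       ("model_pc1", "Model 2 (PC1)")):
        m: ModelReport = result[key]
        star = " **(selected dose summary)**" \
            if m.dose_summary == dose_summary else ""
        lines += [f"## {title}{star}", ""]
        terms = pd.DataFrame(m.terms)
        lines += [_markdown_table(terms), ""]
        lines += [f"R^2 = {m.r_squared:.3f}; bias-corrected R^2 = "
                  f"{m.r_squared_corrected:.3f} "
                  f"({m.bootstrap_B} bootstrap resamples); "
                  f"MSE = {m.mse:.1f}; AIC = {m.aic:.1f}", ""]
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write the run directory.

    Returns a dict of output paths plus per-stage counts.  Idempotent for
    fixed configuration and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "versions": {
        "lymphokinetics": __version__,
        "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {}}
    t0 = time.time()

    # -- simulate ----------------------------------------------------------
    cc = config.cohort_config or CohortConfig(
        n_patients=config.n_patients, fit_window=config.window,
        seed=config.seed)
    cohort = generate_cohort(cc)
    paths = {}
    for name, df in (("blood", cohort.blood), ("clinical", cohort.clinical),
                     ("dvh", cohort.dvh), ("truth", cohort.truth)):
        p = out / f"{name}.csv"
        _write_csv(df, p)
        paths[name] = p
    manifest["stages"]["simulate"] = {
        "n_patients": int(cc.n_patients),
        "elapsed_s": round(time.time() - t0, 3)}
    log.info("simulate: %d patients", cc.n_patients)

    # -- endpoints ---------------------------------------------------------
    t1 = time.time()
    series, excluded = read_blood_csv(paths["blood"])
    endpoints, fit_excluded = compute_endpoints(series.values(),
                                                window=config.window)
    exclusions = pd.concat([excluded, fit_excluded], ignore_index=True)
    _write_csv(endpoints, out / "endpoints.csv")
    _write_csv(exclusions, out / "exclusions.csv")
    paths["endpoints"] = out / "endpoints.csv"
    n_success = int((endpoints["status"] == "success").sum())
    manifest["stages"]["endpoints"] = {
        "n_series": len(series), "n_excluded": len(exclusions),
        "n_fit_success": n_success,
        "status_counts": endpoints["status"].value_counts().to_dict(),
        "elapsed_s": round(time.time() - t1, 3)}
    log.info("endpoints: %d/%d successful fits", n_success, len(series))

    # -- dvh ---------------------------------------------------------------
    t2 = time.time()
    dvh_long = read_dvh_csv(paths["dvh"])
    clinical = read_clinical_csv(paths["clinical"])
    n_records = validate_dvh_table(dvh_long)
    if config.eqd2:
        dvh_used = eqd2_transform_table(dvh_long, clinical)
    else:
        dvh_used = dvh_long
    _write_csv(dvh_used, out / "dvh_eqd2.csv")
    edric_df = edric_table(dvh_long, clinical)
    _write_csv(edric_df, out / "edric.csv")
    paths["dvh_eqd2"] = out / "dvh_eqd2.csv"
    manifest["stages"]["dvh"] = {
        "n_records": n_records, "eqd2": bool(config.eqd2),
        "elapsed_s": round(time.time() - t2, 3)}
    log.info("dvh: %d records validated (EQD2 %s)", n_records,
             "on" if config.eqd2 else "off")

    # -- analyze -----------------------------------------------------------
    t3 = time.time()
    result = analyze_tables(endpoints, clinical, dvh_used,
                            bootstrap_B=config.bootstrap_B, seed=config.seed,
                            pca_include_ptv=config.pca_include_ptv)
    _write_csv(result["screen"], out / "screen_r2.csv")
    _write_csv(result["ancova"], out / "ancova.csv")
    _write_csv(result["spearman"], out / "spearman.csv")
    pca = result["pca"]
    _write_json({
        "metrics": pca.metric_names,
        "pc1_loadings": [float(v) for v in pca.loadings[:, 0]],
        "explained_fraction": [float(v) for v in pca.explained_fraction],
    }, out / "pca.json")
    _write_json(_model_report_json(result, config.seed),
                out / "model_report.json")
    _stage_write(out / "report.md",
                 lambda p: p.write_text(
                     render_report(result, config.dose_summary)))
    manifest["stages"]["analyze"] = {
        "n_complete_case": int(result["model_pc1"].n),
        "bootstrap_B": config.bootstrap_B,
        "elapsed_s": round(time.time() - t3, 3)}
    log.info("analyze: %d complete cases", result["model_pc1"].n)

    manifest["inputs"] = {k: _sha256(p) for k, p in sorted(paths.items())}
    _write_json(manifest, out / "manifest.json")
    outputs = {name: out / f"{name}" for name in (
        "screen_r2.csv", "ancova.csv", "spearman.csv", "pca.json",
        "model_report.json", "report.md")}
    outputs.update(paths)
    outputs["manifest"] = out / "manifest.json"
    return {"outputs": outputs, "manifest": manifest, "result": result}
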