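"""Association analyses linking dosimetry to percentage ALC loss.

The pipeline mirrors how dose-volume predictors of radiation-induced
lymphopenia are screened and modelled on a complete-case analysis table
(one row per patient with a successful decay fit):

* a univariable screen fitting ``percent_loss ~ CRT + metric`` for each
  DVH metric (plus EDRIC and PTV volume) within each technique stratum,
  ranked by model R^2;
* ANCOVA comparing each metric between VMAT and IMRT plans adjusted for
  PTV volume;
* Spearman correlations of each metric with both candidate endpoints
  (percentage loss and nadir);
* PCA of the standardized, highly collinear metric matrix, keeping the
  first principal component as a one-number dose summary;
* multivariable linear models ``percent_loss ~ CRT + baseline ALC +
  (EDRIC | PC1)`` with internal validation by Harrell's optimism
  bootstrap.

R^2 is the ordinary coefficient of determination; MSE is RSS/n on the
training data; AIC uses the Gaussian log-likelihood convention that
counts the error variance as a parameter, so differences match those of
standard statistical environments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError

__all__ = [
    "PCAResult",
    "ModelReport",
    "build_analysis_table",
    "univariable_screen",
    "ancova_plan_comparison",
    "spearman_endpoint_comparison",
    "pca_dose",
    "fit_multivariable",
    "optimism_corrected_r2",
    "gaussian_aic",
]

_VAR_EPS = 1e-12


def build_analysis_table(
    endpoints: pd.DataFrame,
    clinical: pd.DataFrame,
    dvh_wide: pd.DataFrame,
    edric: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Merge endpoints, clinical covariates and wide DVH metrics into the
    complete-case analysis table.

    Only patients whose decay fit succeeded are retained, and rows with
    any missing modelled value are dropped.  Returns the table and the
    list of DVH metric column names.
    """
    ok = endpoints.loc[endpoints["status"] == "success",
                       ["patient_id", "percent_loss", "nadir",
                        "baseline_alc"]].copy()
    for df in (ok, clinical, dvh_wide):
        df["patient_id"] = df["patient_id"].astype(str)
    table = ok.merge(clinical, on="patient_id", how="inner")
    table = table.merge(dvh_wide, on="patient_id", how="inner")
    if edric is not None:
        e = edric.copy()
        e["patient_id"] = e["patient_id"].astype(str)
        table = table.merge(e[["patient_id", "edric"]], on="patient_id",
                            how="inner")
    metric_cols = [c for c in dvh_wide.columns if c != "patient_id"]
    modelled = (["percent_loss", "nadir", "baseline_alc", "crt",
                 "technique", "ptv_cm3"] + metric_cols
                + (["edric"] if edric is not None else []))
    table = table.dropna(subset=[c for c in modelled if c in table.columns])
    table = table.reset_index(drop=True)
    return table, metric_cols


def _design(table: pd.DataFrame, cols: Sequence[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(table))]
                        + [pd.to_numeric(table[c]).to_numpy(float)
                           for c in cols])
    return X


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < _VAR_EPS:
        return 1.0 if float(np.sum(resid**2)) < 1e-8 else 0.0
    return 1.0 - float(np.sum(resid**2)) / sst


def univariable_screen(
    table: pd.DataFrame,
    metric_cols: Sequence[str],
    *,
    extra_cols: Sequence[str] = ("edric", "ptv_cm3"),
    stratify_col: str | None = "technique",
    outcome: str = "percent_loss",
    adjust_col: str = "crt",
    min_rows: int = 10,
) -> pd.DataFrame:
    """Per-metric predictive screen: R^2 of ``outcome ~ CRT + metric``.

    Run within each stratum (RT technique by default).  Metrics without
    variance in a stratum are flagged ``degenerate`` and skipped rather
    than failing the screen.
    """
    cols = list(metric_cols) + [c for c in extra_cols if c in table.columns]
    strata = ([(s, grp) for s, grp in table.groupby(stratify_col, sort=True)]
              if stratify_col else [("all", table)])
    rows = []
    for stratum, grp in strata:
        if len(grp) < min_rows:
            raise AnalysisError(
                f"stratum {stratum!r} has {len(grp)} rows; "
                f"need at least {min_rows}")
        y = grp[outcome].to_numpy(float)
        adj = pd.to_numeric(grp[adjust_col]).to_numpy(float)
        for col in cols:
            x = pd.to_numeric(grp[col]).to_numpy(float)
            if np.var(x) < _VAR_EPS:
                rows.append({"stratum": stratum, "metric": col,
                             "r_squared": np.nan, "n": len(grp),
                             "degenerate": True})
                continue
            X = np.column_stack([np.ones_like(y), adj, x])
            rows.append({"stratum": stratum, "metric": col,
                         "r_squared": _ols_r2(y, X), "n": len(grp),
                         "degenerate": False})
    out = pd.DataFrame(rows)
    # stable ordering: structure, then threshold, then stratum
    out["_order"] = out["metric"].map({c: i for i, c in enumerate(cols)})
    out = out.sort_values(["_order", "stratum"]).drop(columns="_order")
    return out.reset_index(drop=True)


def ancova_plan_comparison(
    table: pd.DataFrame,
    metric_cols: Sequence[str],
    *,
    technique_col: str = "technique",
    adjust_col: str = "ptv_cm3",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Technique contrast (VMAT vs IMRT) for each metric, adjusted for
    PTV volume: OLS of ``metric ~ technique + ptv``.

    Returns the VMAT-vs-IMRT coefficient with 95 % CI and p-value per
    metric; optional Benjamini-Hochberg adjusted p-values.
    """
    levels = sorted(table[technique_col].astype(str).unique())
    if len(levels) < 2:
        raise AnalysisError(
            f"ANCOVA requires both techniques; found only {levels}")
    is_vmat = (table[technique_col].astype(str) == "VMAT").to_numpy(float)
    ptv = pd.to_numeric(table[adjust_col]).to_numpy(float)
    X = sm.add_constant(np.column_stack([is_vmat, ptv]))
    rows = []
    for col in metric_cols:
        y = pd.to_numeric(table[col]).to_numpy(float)
        if np.var(y) < _VAR_EPS:
            rows.append({"metric": col, "coef_vmat": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "p_value": np.nan, "n": len(table)})
            continue
        fit = sm.OLS(y, X).fit()
        ci = fit.conf_int()[1]
        rows.append({"metric": col, "coef_vmat": float(fit.params[1]),
                     "ci_low": float(ci[0]), "ci_high": float(ci[1]),
                     "p_value": float(fit.pvalues[1]), "n": len(table)})
    out = pd.DataFrame(rows)
    if bh_adjust:
        mask = out["p_value"].notna()
        adj = np.full(len(out), np.nan)
        if mask.any():
            adj[mask.to_numpy()] = multipletests(
                out.loc[mask, "p_value"], method="fdr_bh")[1]
        out["p_bh"] = adj
    return out


def spearman_endpoint_comparison(
    table: pd.DataFrame,
    metric_cols: Sequence[str],
    *,
    loss_col: str = "percent_loss",
    nadir_col: str = "nadir",
) -> pd.DataFrame:
    """Spearman correlation of each metric with the percentage-loss and
    nadir endpoints; constant metrics yield missing correlations."""
    if len(table) < 3:
        raise AnalysisError("Spearman comparison needs at least 3 rows")
    loss = pd.to_numeric(table[loss_col]).to_numpy(float)
    nad = pd.to_numeric(table[nadir_col]).to_numpy(float)
    rows = []
    for col in metric_cols:
        x = pd.to_numeric(table[col]).to_numpy(float)
        if np.var(x) < _VAR_EPS:
            rows.append({"metric": col, "rho_percent_loss": np.nan,
                         "rho_nadir": np.nan, "n": len(table)})
            continue
        rho_l = scipy.stats.spearmanr(x, loss).statistic
        rho_n = scipy.stats.spearmanr(x, nad).statistic
        rows.append({"metric": col, "rho_percent_loss": float(rho_l),
                     "rho_nadir": float(rho_n), "n": len(table)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PCAResult:
    """Principal components of the standardized dose-metric matrix."""

    metric_names: list[str]
    loadings: np.ndarray          # columns = components, orthonormal
    explained_fraction: np.ndarray
    pc1_scores: np.ndarray

    @property
    def pc1_explained(self) -> float:
        return float(self.explained_fraction[0])


def pca_dose(
    table: pd.DataFrame,
    metric_cols: Sequence[str],
    *,
    include_ptv: bool = False,
    orient_col: str = "body_Dmean",
) -> PCAResult:
    """PCA of the z-standardized DVH metrics (correlation-matrix PCA;
    the metrics mix Gy and % units, so standardization is obligatory).

    PC1's sign is oriented so its correlation with the mean body dose is
    positive: higher PC1 means a more dose-intense plan.  Zero-variance
    metrics are dropped with a warning.
    """
    cols = list(metric_cols) + (["ptv_cm3"] if include_ptv else [])
    keep = []
    for c in cols:
        if np.var(pd.to_numeric(table[c]).to_numpy(float)) < _VAR_EPS:
            warnings.warn(f"PCA: dropping zero-variance metric {c!r}")
        else:
            keep.append(c)
    if len(keep) < 2:
        raise AnalysisError("PCA needs at least 2 metrics with variance")
    if len(keep) > len(table):
        warnings.warn("PCA: more metrics than rows; correlation PCA "
                      "proceeds but trailing components are null")
    X = table[keep].apply(pd.to_numeric).to_numpy(float)
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    corr = (Z.T @ Z) / (len(table) - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    scores = Z @ eigvecs
    orient = orient_col if orient_col in keep else keep[0]
    ref = pd.to_numeric(table[orient]).to_numpy(float)
    if np.corrcoef(scores[:, 0], ref)[0, 1] < 0:
        eigvecs = eigvecs.copy()
        eigvecs[:, 0] = -eigvecs[:, 0]
        scores = scores.copy()
        scores[:, 0] = -scores[:, 0]
    return PCAResult(keep, eigvecs, eigvals / eigvals.sum(), scores[:, 0])


def gaussian_aic(n: int, rss: float, n_coef: int) -> float:
    """AIC of a Gaussian linear model: ``n*ln(2*pi) + n*ln(RSS/n) + n +
    2*(n_coef + 1)`` — the error variance counts as a parameter."""
    return (n * np.log(2.0 * np.pi) + n * np.log(rss / n) + n
            + 2.0 * (n_coef + 1))


@dataclass(frozen=True)
class ModelReport:
    """One fitted linear model with internal validation."""

    terms: list[dict]
    r_squared: float
    r_squared_corrected: float
    optimism: float
    mse: float
    aic: float
    n: int
    bootstrap_B: int
    bootstrap_skipped: int
    seed: int
    dose_summary: str

    def to_dict(self) -> dict:
        return {
            "dose_summary": self.dose_summary,
            "n": self.n,
            "terms": self.terms,
            "r_squared": self.r_squared,
            "r_squared_corrected": self.r_squared_corrected,
            "optimism": self.optimism,
            "mse": self.mse,
            "aic": self.aic,
            "bootstrap_B": self.bootstrap_B,
            "bootstrap_skipped": self.bootstrap_skipped,
            "seed": self.seed,
        }


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        for j in range(X.shape[1]):
            Xr = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(Xr) == rank:
                collinear.append(names[j])
        raise AnalysisError(
            "rank-deficient design; collinear terms: "
            + ", ".join(collinear or list(names)))


def fit_multivariable(
    table: pd.DataFrame,
    dose_summary: str = "edric",
    *,
    outcome: str = "percent_loss",
    clinical_cols: Sequence[str] = ("crt", "baseline_alc"),
    bootstrap_B: int = 300,
    seed: int = 7,
) -> ModelReport:
    """OLS of percentage ALC loss on CRT, baseline ALC and one dose
    summary (EDRIC or PC1), with optimism-corrected R^2.

    ``dose_summary`` names a column of the table (``edric`` or ``pc1``).
    Raises :class:`AnalysisError` on a rank-deficient design, naming the
    collinear terms.
    """
    if dose_summary not in table.columns:
        raise AnalysisError(f"dose summary column {dose_summary!r} missing")
    pred_cols = list(clinical_cols) + [dose_summary]
    names = ["intercept"] + pred_cols
    y = pd.to_numeric(table[outcome]).to_numpy(float)
    X = _design(table, pred_cols)
    _check_rank(X, names)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    terms = []
    for j, name in enumerate(names):
        terms.append({"name": name, "coef": float(fit.params[j]),
                      "ci_low": float(ci[j][0]), "ci_high": float(ci[j][1]),
                      "p_value": float(fit.pvalues[j])})
    n = len(y)
    rss = float(np.sum(fit.resid**2))
    r2 = float(fit.rsquared)
    corrected, optimism, skipped = optimism_corrected_r2(
        y, X, B=bootstrap_B, seed=seed)
    return ModelReport(
        terms=terms, r_squared=r2, r_squared_corrected=corrected,
        optimism=optimism, mse=rss / n, aic=gaussian_aic(n, rss, X.shape[1]),
        n=n, bootstrap_B=bootstrap_B, bootstrap_skipped=skipped, seed=seed,
        dose_summary=dose_summary)


def optimism_corrected_r2(
    y: np.ndarray,
    X: np.ndarray,
    *,
    B: int = 300,
    seed: int = 7,
    sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> tuple[float, float, int]:
    """Harrell's optimism bootstrap for R^2 of an OLS model.

    For each of B bootstrap resamples of patient rows: refit, record the
    resample R^2 minus the R^2 of the resample coefficients evaluated on
    the original data.  The mean of those differences is the optimism;
    corrected R^2 = apparent R^2 - optimism.  Deterministic given the
    seed.  Degenerate resamples (constant outcome or rank-deficient
    design) are skipped and counted; a warning is raised when more than
    10 % are skipped.

    R^2 is the squared correlation between predictions and
    observations; on the training side this equals the usual
    1 - SSE/SST of OLS, and on the evaluation side it is the standard
    R^2 definition for out-of-sample predictions.  With this convention
    the corrected R^2 is approximately zero (slightly negative) when the
    outcome is independent of the predictors.

    ``sampler(rng, n) -> index array`` can replace the default
    with-replacement row sampler (used for exactness tests).

    Returns ``(corrected, optimism, n_skipped)``.
    """
    if B < 1:
        raise AnalysisError(f"bootstrap_B must be >= 1, got {B!r}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    beta_app, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst < _VAR_EPS:
        raise AnalysisError("outcome has no variance")
    apparent = 1.0 - float(np.sum((y - X @ beta_app) ** 2)) / sst
    optimisms = []
    skipped = 0
    for _ in range(B):
        idx = (sampler(rng, n) if sampler is not None
               else rng.integers(0, n, size=n))
        yb, Xb = y[idx], X[idx]
        sst_b = float(np.sum((yb - yb.mean()) ** 2))
        if sst_b < _VAR_EPS or np.linalg.matrix_rank(Xb) < p:
            skipped += 1
            continue
        beta_b, _, _, _ = np.linalg.lstsq(Xb, yb, rcond=None)
        r2_boot = 1.0 - float(np.sum((yb - Xb @ beta_b) ** 2)) / sst_b
        pred = X @ beta_b
        if float(np.var(pred)) < _VAR_EPS:
            r2_orig = 0.0
        else:
            r2_orig = float(np.corrcoef(pred, y)[0, 1]) ** 2
        optimisms.append(r2_boot - r2_orig)
    if skipped > 0.1 * B:
        warnings.warn(f"optimism bootstrap: {skipped}/{B} degenerate "
                      "resamples skipped")
    if not optimisms:
        raise AnalysisError("all bootstrap resamples were degenerate")
    optimism = float(np.mean(optimisms))
    return apparent - optimism, optimism, skipped
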