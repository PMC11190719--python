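"""Screen, ANCOVA, Spearman, PCA and multivariable modelling."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from lymphokinetics.analysis import (
    ancova_plan_comparison, build_analysis_table, fit_multivariable,
    gaussian_aic, optimism_corrected_r2, pca_dose,
    spearman_endpoint_comparison, univariable_screen,
)
from lymphokinetics.dosimetry import dvh_wide, edric_table
from lymphokinetics.errors import AnalysisError
from lymphokinetics.synthetic import (CohortConfig, default_dvh_model,
                                      generate_cohort,
                                      population_metric_covariance,
                                      STRUCTURES)


def _screen_table(rng, n=80):
    crt = (rng.random(n) < 0.4).astype(float)
    metric = rng.normal(20, 5, n)
    other = rng.normal(0, 1, n)
    return pd.DataFrame({
        "percent_loss": 10 + 5 * crt + 2 * metric,
        "crt": crt,
        "technique": np.where(rng.random(n) < 0.5, "VMAT", "IMRT"),
        "metric_exact": metric,
        "metric_noise": other,
        "metric_const": np.full(n, 7.0),
    })


class TestUnivariableScreen:
    def test_exact_linear_relation_gives_r2_of_one(self, rng):
        t = _screen_table(rng)
        out = univariable_screen(
            t, ["metric_exact", "metric_noise"], extra_cols=(),
            stratify_col=None)
        r2 = out.set_index("metric")["r_squared"]
        assert r2["metric_exact"] == pytest.approx(1.0, abs=1e-9)
        assert r2["metric_noise"] < 0.9

    def test_constant_metric_flagged_degenerate(self, rng):
        t = _screen_table(rng)
        out = univariable_screen(t, ["metric_const"], extra_cols=(),
                                 stratify_col=None)
        assert out["degenerate"].all()
        assert out["r_squared"].isna().all()

    def test_small_stratum_rejected(self, rng):
        t = _screen_table(rng, n=8)
        with pytest.raises(AnalysisError, match="rows"):
            univariable_screen(t, ["metric_exact"], extra_cols=(),
                               stratify_col=None)

    def test_r2_ranking_tracks_configured_loadings(self):
        # metrics more strongly loaded on the latent plan factor should
        # screen higher; compare against the population correlations
        from lymphokinetics.kinetics import compute_endpoints
        cfg = CohortConfig(n_patients=1200, seed=4)
        cohort = generate_cohort(cfg)
        ep, _ = compute_endpoints(cohort.series().values())
        table, cols = build_analysis_table(ep, cohort.clinical,
                                           dvh_wide(cohort.dvh))
        screen = univariable_screen(table, cols, extra_cols=(),
                                    stratify_col=None)
        names, cov = population_metric_covariance(cfg)
        models = default_dvh_model(cfg)
        lam = np.concatenate([models[s].loadings for s in STRUCTURES])
        rho = dict(zip(names, lam / np.sqrt(np.diag(cov))))
        merged = screen.dropna(subset=["r_squared"]).copy()
        merged["rho"] = merged["metric"].map(rho)
        agreement = scipy.stats.spearmanr(merged["r_squared"],
                                          merged["rho"]).statistic
        assert agreement > 0.8


class TestAncova:
    def test_metric_explained_by_ptv_alone_has_zero_contrast(self, rng):
        n = 60
        ptv = rng.uniform(100, 900, n)
        t = pd.DataFrame({
            "technique": np.where(rng.random(n) < 0.5, "VMAT", "IMRT"),
            "ptv_cm3": ptv,
            "metric": 0.05 * ptv,
        })
        out = ancova_plan_comparison(t, ["metric"])
        assert out.loc[0, "coef_vmat"] == pytest.approx(0.0, abs=1e-8)

    def test_single_technique_rejected(self, rng):
        t = pd.DataFrame({"technique": ["IMRT"] * 20,
                          "ptv_cm3": rng.uniform(100, 900, 20),
                          "metric": rng.normal(size=20)})
        with pytest.raises(AnalysisError, match="technique"):
            ancova_plan_comparison(t, ["metric"])

    def test_configured_vmat_shift_recovered(self):
        shift = {f"body:{m}": 8.0 for m in ("V0.5", "V1", "V2", "V5")}
        cfg = CohortConfig(n_patients=800, seed=9, technique_effects=shift)
        cohort = generate_cohort(cfg)
        t = dvh_wide(cohort.dvh).merge(cohort.clinical, on="patient_id")
        out = ancova_plan_comparison(t, ["body_V5", "lungs_sum_V20"])
        row = out.set_index("metric").loc["body_V5"]
        assert row["ci_low"] <= 8.0 <= row["ci_high"]
        null_row = out.set_index("metric").loc["lungs_sum_V20"]
        assert abs(null_row["coef_vmat"]) < 1.5


class TestSpearman:
    def test_monotone_metric_has_unit_correlation(self):
        t = pd.DataFrame({"percent_loss": np.arange(10.0),
                          "nadir": np.arange(10.0)[::-1],
                          "metric": np.arange(10.0) ** 2})
        out = spearman_endpoint_comparison(t, ["metric"])
        assert out.loc[0, "rho_percent_loss"] == pytest.approx(1.0)
        assert out.loc[0, "rho_nadir"] == pytest.approx(-1.0)

    def test_constant_metric_reported_missing(self, rng):
        t = pd.DataFrame({"percent_loss": rng.normal(size=20),
                          "nadir": rng.normal(size=20),
                          "metric": np.ones(20)})
        out = spearman_endpoint_comparison(t, ["metric"])
        assert np.isnan(out.loc[0, "rho_percent_loss"])

    def test_independent_metric_near_zero(self, rng):
        n = 2000
        t = pd.DataFrame({"percent_loss": rng.normal(size=n),
                          "nadir": rng.normal(size=n),
                          "metric": rng.normal(size=n)})
        out = spearman_endpoint_comparison(t, ["metric"])
        assert abs(out.loc[0, "rho_percent_loss"]) < 0.05
        assert abs(out.loc[0, "rho_nadir"]) < 0.05


class TestPca:
    def test_perfectly_correlated_metrics_give_single_component(self, rng):
        x = rng.normal(size=100)
        t = pd.DataFrame({"m1": x, "m2": 3 * x + 1, "body_Dmean": x})
        res = pca_dose(t, ["m1", "m2"])
        assert res.pc1_explained == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal_and_scores_reconstruct(self, rng):
        X = rng.normal(size=(200, 6))
        cols = [f"m{i}" for i in range(6)]
        t = pd.DataFrame(X, columns=cols)
        res = pca_dose(t, cols)
        V = res.loadings
        assert np.allclose(V.T @ V, np.eye(6), atol=1e-9)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        assert np.allclose(Z @ V[:, 0], res.pc1_scores, atol=1e-9)
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)

    def test_pc1_oriented_with_mean_body_dose(self, rng):
        x = rng.normal(size=300)
        t = pd.DataFrame({"body_Dmean": x, "other": -x + 0.1
                          * rng.normal(size=300)})
        res = pca_dose(t, ["body_Dmean", "other"])
        assert np.corrcoef(res.pc1_scores, x)[0, 1] > 0

    def test_zero_variance_metric_dropped_with_warning(self, rng):
        t = pd.DataFrame({"m1": rng.normal(size=50),
                          "m2": rng.normal(size=50),
                          "m3": np.ones(50)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = pca_dose(t, ["m1", "m2", "m3"])
        assert "m3" not in res.metric_names


class TestMultivariable:
    @staticmethod
    def _exact_table(rng, n=60):
        crt = (rng.random(n) < 0.4).astype(float)
        baseline = rng.uniform(1.0, 3.0, n)
        edric = rng.uniform(2.0, 8.0, n)
        loss = 16.15 + 7.00 * crt + 7.83 * baseline + 2.37 * edric
        return pd.DataFrame({"percent_loss": loss, "crt": crt,
                             "baseline_alc": baseline, "edric": edric})

    def test_noiseless_relation_recovered_exactly(self, rng):
        t = self._exact_table(rng)
        report = fit_multivariable(t, "edric", bootstrap_B=5, seed=1)
        coefs = {term["name"]: term["coef"] for term in report.terms}
        assert coefs["intercept"] == pytest.approx(16.15, abs=1e-8)
        assert coefs["crt"] == pytest.approx(7.00, abs=1e-8)
        assert coefs["baseline_alc"] == pytest.approx(7.83, abs=1e-8)
        assert coefs["edric"] == pytest.approx(2.37, abs=1e-8)
        assert report.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_ci_brackets_coefficient(self, rng):
        t = self._exact_table(rng)
        t["percent_loss"] += rng.normal(0, 5, len(t))
        report = fit_multivariable(t, "edric", bootstrap_B=20, seed=1)
        for term in report.terms:
            assert term["ci_low"] <= term["coef"] <= term["ci_high"]

    def test_corrected_r2_not_above_apparent(self, rng):
        t = self._exact_table(rng, n=80)
        t["percent_loss"] += rng.normal(0, 8, len(t))
        report = fit_multivariable(t, "edric", bootstrap_B=200, seed=1)
        assert report.r_squared_corrected <= report.r_squared + 0.02

    def test_constant_dose_summary_rejected(self, rng):
        t = self._exact_table(rng)
        t["edric"] = 5.0
        with pytest.raises(AnalysisError, match="collinear"):
            fit_multivariable(t, "edric", bootstrap_B=5, seed=1)

    def test_r2_and_aic_invariant_to_predictor_rescaling(self, rng):
        t = self._exact_table(rng)
        t["percent_loss"] += rng.normal(0, 5, len(t))
        a = fit_multivariable(t, "edric", bootstrap_B=1, seed=1)
        t2 = t.assign(edric=t["edric"] * 1000.0 + 5.0)
        b = fit_multivariable(t2, "edric", bootstrap_B=1, seed=1)
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-9)
        assert a.aic == pytest.approx(b.aic, abs=1e-6)

    def test_screen_r2_matches_direct_model_fit(self, cohort, endpoints):
        # dual route: the screen's R^2 for EDRIC must equal an
        # independently fitted OLS of loss on CRT + EDRIC
        edric = edric_table(cohort.dvh, cohort.clinical)
        table, cols = build_analysis_table(endpoints, cohort.clinical,
                                           dvh_wide(cohort.dvh), edric)
        screen = univariable_screen(table, [], extra_cols=("edric",),
                                    stratify_col=None)
        r2_screen = screen.set_index("metric").loc["edric", "r_squared"]
        X = sm.add_constant(np.column_stack([
            table["crt"].astype(float), table["edric"]]))
        r2_direct = sm.OLS(table["percent_loss"].to_numpy(), X).fit().rsquared
        assert r2_screen == pytest.approx(r2_direct, abs=1e-10)


class TestOptimismBootstrap:
    def test_identity_resample_has_zero_optimism(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 1, 40)
        corrected, optimism, skipped = optimism_corrected_r2(
            y, X, B=1, seed=0, sampler=lambda r, n: np.arange(n))
        assert optimism == pytest.approx(0.0, abs=1e-12)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        apparent = 1 - np.sum((y - X @ beta) ** 2) / np.sum(
            (y - y.mean()) ** 2)
        assert corrected == pytest.approx(apparent, abs=1e-12)
        assert skipped == 0

    def test_deterministic_given_seed(self, rng):
        X = np.column_stack([np.ones(50), rng.normal(size=(50, 3))])
        y = rng.normal(size=50)
        a = optimism_corrected_r2(y, X, B=100, seed=5)
        b = optimism_corrected_r2(y, X, B=100, seed=5)
        assert a == b

    def test_invalid_b_rejected(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        with pytest.raises(AnalysisError):
            optimism_corrected_r2(rng.normal(size=20), X, B=0, seed=0)


def test_gaussian_aic_matches_r_convention():
    # n=10, rss=10, 2 coefficients: n ln(2pi) + n ln(1) + n + 2*3
    assert gaussian_aic(10, 10.0, 2) == pytest.approx(
        10 * np.log(2 * np.pi) + 10 + 6)
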