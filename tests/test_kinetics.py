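"""Decay fitting, baseline selection and the percentage-loss endpoint."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lymphokinetics.errors import BaselineMissingError, DomainError
from lymphokinetics.kinetics import (
    STATUS_FAIL_B_RANGE, STATUS_FAIL_INSUFFICIENT, STATUS_FAIL_R2,
    BloodCountSeries, auc_closed_form, ctcae_grade, fit_decay, nadir,
    percent_alc_loss, select_baseline,
)

WEEKLY = np.array([0.0, 7, 14, 21, 28, 35, 42])


def series(times, values, pid="p"):
    return BloodCountSeries(pid, np.asarray(times, float),
                            np.asarray(values, float))


class TestBloodCountSeries:
    def test_duplicate_days_are_averaged(self):
        s = series([0, 0, 7], [2.0, 3.0, 1.0])
        assert np.allclose(s.times, [0, 7])
        assert np.allclose(s.values, [2.5, 1.0])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            series([0, 7], [2.0, -0.1])


class TestSelectBaseline:
    @pytest.mark.parametrize(
        "times, values, expected",
        [
            # day 8 too late, -30 further from RT start than day 1
            ([-30, 1, 8], [2.4, 2.1, 1.5], (2.1, 1.0)),
            ([-10, -3], [2.0, 2.2], (2.2, -3.0)),
            # tie in distance resolved toward the later measurement
            ([-1, 1], [1.8, 1.9], (1.9, 1.0)),
        ],
    )
    def test_picks_count_closest_to_rt_start(self, times, values, expected):
        assert select_baseline(series(times, values)) == expected

    def test_no_eligible_measurement_raises(self):
        with pytest.raises(BaselineMissingError):
            select_baseline(series([3, 10], [2.0, 1.0]))

    def test_counts_older_than_91_days_ineligible(self):
        with pytest.raises(BaselineMissingError):
            select_baseline(series([-120, 5], [2.0, 1.0]))


class TestFitDecay:
    @pytest.mark.parametrize("a,b,c", [
        (1.6, 0.10, 0.40),
        (2.2, 0.05, 0.10),
        (0.9, 0.30, 0.75),
    ])
    def test_noiseless_series_recovers_parameters(self, a, b, c):
        v = a * np.exp(-b * WEEKLY) + c
        fit = fit_decay(series(WEEKLY, v), (float(v[0]), 0.0))
        assert fit.ok
        assert abs(fit.a - a) < 1e-6
        assert abs(fit.b - b) < 1e-6
        assert abs(fit.c - c) < 1e-6
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_super_fast_decay_flagged_out_of_range(self):
        t = np.array([0, 1, 2, 3, 5, 7, 10, 14, 21, 28, 35, 42], float)
        v = 1.6 * np.exp(-1.4 * t) + 0.4
        fit = fit_decay(series(t, v), (2.0, 0.0))
        assert fit.status == STATUS_FAIL_B_RANGE
        assert fit.b > 1.0

    def test_rising_counts_fail_qc(self):
        v = 2.0 * (1 + 0.012 * WEEKLY)
        fit = fit_decay(series(WEEKLY, v), (2.0, 0.0))
        assert fit.status in (STATUS_FAIL_B_RANGE, STATUS_FAIL_R2)

    def test_constant_series_is_a_perfect_flat_fit(self):
        v = np.full_like(WEEKLY, 2.0)
        fit = fit_decay(series(WEEKLY, v), (2.0, 0.0))
        assert np.allclose(fit.predict(WEEKLY), 2.0, atol=1e-6)
        assert fit.r_squared == 1.0
        assert fit.ok
        loss = percent_alc_loss(fit.a, fit.b, fit.c, 2.0, fit.window_end_T)
        assert abs(loss) < 1e-5

    def test_fewer_than_three_points_is_insufficient(self):
        fit = fit_decay(series([0, 21, 60], [2.0, 1.0, 1.5]), (2.0, 0.0))
        assert fit.status == STATUS_FAIL_INSUFFICIENT
        assert fit.n_points == 2  # day 60 outside the 45-day window

    def test_pre_rt_baseline_mapped_to_day_zero(self):
        # baseline at day -4 is used as the t = 0 anchor
        t = np.array([-4.0, 7, 14, 21, 28])
        v = 1.6 * np.exp(-0.1 * np.array([0.0, 7, 14, 21, 28])) + 0.4
        fit = fit_decay(series(t, v), (float(v[0]), -4.0))
        assert fit.ok
        assert abs(fit.b - 0.1) < 1e-6


class TestAucClosedForm:
    def test_reference_value(self):
        assert auc_closed_form(1.6, 0.1, 0.4, 45) == pytest.approx(
            33.8223, abs=5e-4)

    def test_pure_plateau(self):
        assert auc_closed_form(0.0, 0.3, 0.4, 45) == pytest.approx(18.0)

    def test_zero_rate_limit(self):
        assert auc_closed_form(1.0, 0.0, 1.0, 10) == pytest.approx(20.0)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(DomainError):
            auc_closed_form(1.0, 0.1, 0.5, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(a=st.floats(0, 3), b=st.floats(0, 1), c=st.floats(0, 2),
           T=st.floats(5, 60))
    def test_matches_trapezoidal_integration(self, a, b, c, T):
        t = np.arange(0.0, T + 1e-9, 0.001)
        num = np.trapezoid(a * np.exp(-b * t) + c, t)
        closed = auc_closed_form(a, b, c, float(t[-1]))
        assert closed == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestPercentLoss:
    def test_reference_value(self):
        assert percent_alc_loss(1.6, 0.1, 0.4, 2.0, 45) == pytest.approx(
            62.42, abs=0.01)

    def test_plateau_at_baseline_loses_nothing(self):
        assert percent_alc_loss(0.0, 0.2, 2.0, 2.0, 45) == pytest.approx(0.0)

    def test_invalid_baseline_rejected(self):
        with pytest.raises(DomainError):
            percent_alc_loss(1.0, 0.1, 0.4, 0.0, 45)

    @pytest.mark.parametrize("k", [0.001, 0.5, 1000.0])
    def test_invariant_to_unit_rescaling(self, k):
        ref = percent_alc_loss(1.6, 0.1, 0.4, 2.0, 45)
        scaled = percent_alc_loss(1.6 * k, 0.1, 0.4 * k, 2.0 * k, 45)
        assert scaled == pytest.approx(ref, abs=1e-9)

    def test_strictly_decreasing_in_plateau(self):
        losses = [percent_alc_loss(1.6, 0.1, c, 2.5, 45)
                  for c in (0.0, 0.3, 0.6, 0.9)]
        assert all(x > y for x, y in zip(losses, losses[1:]))

    def test_curve_above_baseline_gives_negative_loss(self):
        assert percent_alc_loss(0.0, 0.1, 2.5, 2.0, 45) < 0


class TestNadirAndGrade:
    def test_minimum_within_window(self):
        s = series([0, 10, 20, 30], [2.0, 1.2, 0.6, 0.9])
        assert nadir(s, 45) == 0.6

    def test_pre_rt_counts_ignored(self):
        s = series([-10, 5], [0.3, 1.1])
        assert nadir(s, 45) == 1.1

    def test_empty_window_raises(self):
        with pytest.raises(DomainError):
            nadir(series([-10, -5], [2.0, 1.9]), 45)

    @pytest.mark.parametrize("value, grade", [
        (0.15, 4), (0.49, 3), (0.54, 2), (0.79, 2), (0.9, 1), (1.2, 0),
    ])
    def test_ctcae_thresholds(self, value, grade):
        assert ctcae_grade(value) == grade

    def test_negative_nadir_rejected(self):
        with pytest.raises(DomainError):
            ctcae_grade(-0.1)


class TestEndpointsTable:
    def test_one_status_per_patient_and_consistent_flags(self, endpoints):
        from lymphokinetics.kinetics import FIT_STATUSES
        assert set(endpoints["status"]) <= set(FIT_STATUSES)
        assert endpoints["patient_id"].is_unique
        finite = endpoints["nadir"].notna()
        assert (endpoints.loc[finite, "severe_ril"]
                == (endpoints.loc[finite, "nadir"] < 0.5)).all()
        ok = endpoints["status"] == "success"
        assert endpoints.loc[ok, "percent_loss"].notna().all()
        assert (endpoints.loc[ok, "r_squared"] >= 0.5).all()
        assert endpoints.loc[ok, "b"].between(0, 1).all()
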