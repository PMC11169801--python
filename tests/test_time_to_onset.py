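"""Onset intervals, Weibull shape-parameter test, profile classes, Kaplan-Meier."""
import math

import numpy as np
import pytest

from faerspv import (
    TTOError,
    TTORecord,
    classify_profile,
    compute_tto,
    km_at,
    km_curve,
    tto_summary,
    weibull_mle,
)


class TestComputeTto:
    def test_calendar_day_difference(self, report_factory):
        cohort = [report_factory(caseid=1, therapy_start="20230101", event_date="20230131")]
        records = compute_tto(cohort)
        assert records == [TTORecord(caseid=1, days=30)]

    def test_event_before_start_excluded(self, report_factory):
        cohort = [report_factory(caseid=1, therapy_start="20230201", event_date="20230101")]
        assert compute_tto(cohort) == []

    @pytest.mark.parametrize("start, event", [
        ("202301", "20230131"),    # month-precision start
        ("20230101", "202303"),    # month-precision event
        ("", "20230131"),          # missing start
        ("20230101", ""),          # missing event
        ("20230231", "20230301"),  # invalid start
    ])
    def test_imprecise_or_missing_dates_excluded(self, report_factory, start, event):
        cohort = [report_factory(caseid=1, therapy_start=start, event_date=event)]
        assert compute_tto(cohort) == []

    def test_same_day_onset_kept_as_zero(self, report_factory):
        cohort = [report_factory(caseid=1, therapy_start="20230115", event_date="20230115")]
        assert compute_tto(cohort) == [TTORecord(caseid=1, days=0)]


class TestTtoSummary:
    def test_median_of_three(self):
        median, q1, q3 = tto_summary([TTORecord(i, d) for i, d in enumerate((10, 20, 30))])
        assert median == 20

    def test_single_value(self):
        assert tto_summary([TTORecord(1, 5)]) == (5, 5, 5)

    def test_empty_raises(self):
        with pytest.raises(TTOError, match="no_valid_tto"):
            tto_summary([])

    def test_weibull_sample_median_near_closed_form(self):
        """Median of Weibull(beta, alpha) is alpha*(ln 2)^(1/beta) ~ 103 for (1.48, 131.9)."""
        rng = np.random.default_rng(7)
        days = 131.9 * rng.weibull(1.48, size=1000)
        median, _, _ = tto_summary([TTORecord(i, d) for i, d in enumerate(days)])
        closed_form = 131.9 * math.log(2) ** (1 / 1.48)
        assert closed_form == pytest.approx(103, abs=1)
        assert abs(median - 103) / 103 < 0.10


class TestWeibullMle:
    def test_exponential_sample_has_unit_shape(self):
        rng = np.random.default_rng(42)
        fit = weibull_mle(rng.exponential(100, size=2000), min_n=10)
        assert 0.93 <= fit.shape_beta <= 1.07
        assert fit.beta_ci[0] <= fit.shape_beta <= fit.beta_ci[1]

    def test_matches_scipy_reference_fit(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        data = 200.0 * rng.weibull(0.9, size=400)
        fit = weibull_mle(data)
        c, loc, scale = stats.weibull_min.fit(data, floc=0)
        assert loc == 0
        assert fit.shape_beta == pytest.approx(c, rel=1e-4)
        assert fit.scale_alpha == pytest.approx(scale, rel=1e-4)

    def test_shape_ci_covers_truth_mostly(self):
        """At n=447 and beta=0.81 the Wald CI should cover the truth ~95% of runs."""
        rng = np.random.default_rng(11)
        covered = 0
        reps = 60
        for _ in range(reps):
            data = 300.0 * rng.weibull(0.81, size=447)
            fit = weibull_mle(data)
            covered += fit.beta_ci[0] <= 0.81 <= fit.beta_ci[1]
        assert covered >= 0.85 * reps

    def test_parameter_recovery_bias_small(self):
        """Shape MLE bias < 5% of truth at n=500 (averaged over replicates)."""
        rng = np.random.default_rng(5)
        for beta in (0.8, 1.0, 1.5):
            estimates = [
                weibull_mle(100.0 * rng.weibull(beta, size=500)).shape_beta
                for _ in range(200)
            ]
            assert abs(np.mean(estimates) - beta) < 0.05 * beta

    def test_zero_days_replaced_not_dropped(self):
        rng = np.random.default_rng(9)
        days = np.concatenate([[0, 0, 0], 50.0 * rng.weibull(1.0, size=200)])
        fit = weibull_mle(days)
        assert fit.n == 203

    def test_degenerate_sample_rejected(self):
        with pytest.raises(TTOError, match="degenerate_sample"):
            weibull_mle([1.0] * 20)

    def test_sample_floor_enforced(self):
        with pytest.raises(TTOError, match="n_below_floor"):
            weibull_mle([1.0, 2.0, 3.0])


class TestClassifyProfile:
    @pytest.mark.parametrize("ci, profile", [
        ((0.75, 0.87), "early_failure"),
        ((0.73, 0.88), "early_failure"),
        ((1.21, 1.76), "wear_out_failure"),
        ((0.9, 1.1), "random_failure"),
        ((1.0, 1.2), "random_failure"),  # boundary: CI touching 1 contains 1
    ])
    def test_profiles(self, ci, profile):
        assert classify_profile(ci) == profile

    def test_exponential_samples_mostly_random_failure(self):
        rng = np.random.default_rng(13)
        hits = sum(
            weibull_mle(rng.exponential(100, size=500)).profile == "random_failure"
            for _ in range(50)
        )
        assert hits >= 0.85 * 50


class TestKaplanMeier:
    def test_ecdf_steps(self):
        curve = km_curve([10.0, 20.0, 30.0, 40.0])
        assert km_at(curve, 25) == pytest.approx(0.5)
        assert km_at(curve, 5) == 0.0
        assert km_at(curve, 40) == pytest.approx(1.0)
        assert km_at(curve, 1000) == pytest.approx(1.0)

    def test_equals_empirical_cdf_without_censoring(self):
        rng = np.random.default_rng(21)
        days = np.round(rng.exponential(80, size=300))
        curve = km_curve(days)
        for t in (0, 10, 50, 100, 400):
            ecdf = np.mean(days <= t)
            assert km_at(curve, t) == pytest.approx(ecdf, abs=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(22)
        curve = km_curve(rng.weibull(1.3, size=200) * 150)
        inc = np.array(curve.cum_incidence)
        assert np.all(np.diff(inc) >= 0)
        assert inc[0] >= 0 and inc[-1] == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(TTOError):
            km_curve([])
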