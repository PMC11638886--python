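"""Time-to-onset: exclusion rules, quartile convention, Weibull, KM, log-rank."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pvsignal.cohort import AnalyticData
from pvsignal.tto import (
    TtoSample,
    classify_failure,
    compute_tto,
    fit_weibull,
    km_curve,
    logrank_test,
    tto_summary,
)


def _analytic(rows):
    """rows: (primaryid, event_dt, start_dt) for duloxetine / Erectile dysfunction."""
    cases = pd.DataFrame(rows, columns=["primaryid", "event_dt", "start_dt"])
    cases["drug"] = "duloxetine"
    pairs = cases[["primaryid", "drug"]].assign(pt="Erectile dysfunction")
    return AnalyticData(pairs=pairs, cases=cases, targets=["duloxetine"])


class TestComputeTto:
    def test_calendar_arithmetic(self):
        an = _analytic([(1, "20230110", "20230101")])
        s = compute_tto(an, "duloxetine", "Erectile dysfunction")
        assert s.days.tolist() == [9]

    def test_event_before_start_excluded_with_reason(self):
        an = _analytic([(1, "20230101", "20230110")])
        s = compute_tto(an, "duloxetine", "Erectile dysfunction")
        assert s.n == 0
        assert s.exclusions["event_precedes_start"] == 1

    def test_partial_event_date_excluded(self):
        an = _analytic([(1, "202301", "20230101")])
        s = compute_tto(an, "duloxetine", "Erectile dysfunction")
        assert s.exclusions["partial_date"] == 1

    def test_missing_date_excluded_as_invalid(self):
        an = _analytic([(1, "", "20230101"), (2, "20230110", "baddate")])
        s = compute_tto(an, "duloxetine", "Erectile dysfunction")
        assert s.exclusions["invalid_date"] == 2

    def test_zero_day_maps_to_one_by_default(self):
        an = _analytic([(1, "20230101", "20230101")])
        s = compute_tto(an, "duloxetine", "Erectile dysfunction")
        assert s.days.tolist() == [1]

    def test_zero_day_exclude_mode(self):
        an = _analytic([(1, "20230101", "20230101")])
        s = compute_tto(an, "duloxetine", "Erectile dysfunction", zero_day="exclude")
        assert s.n == 0 and s.exclusions["same_day_excluded"] == 1

    def test_tally_plus_retained_equals_input(self):
        rows = [
            (1, "20230110", "20230101"),
            (2, "202301", "20230101"),
            (3, "20230101", "20230110"),
            (4, "", "20230101"),
            (5, "20230301", "20230101"),
        ]
        an = _analytic(rows)
        s = compute_tto(an, "duloxetine", "Erectile dysfunction")
        assert s.n + sum(s.exclusions.values()) == len(rows)

    def test_cases_without_the_pt_tallied(self):
        cases = pd.DataFrame(
            [(1, "20230110", "20230101"), (2, "20230110", "20230101")],
            columns=["primaryid", "event_dt", "start_dt"],
        )
        cases["drug"] = "duloxetine"
        pairs = pd.DataFrame(
            [(1, "duloxetine", "Erectile dysfunction"), (2, "duloxetine", "Nausea")],
            columns=["primaryid", "drug", "pt"],
        )
        an = AnalyticData(pairs=pairs, cases=cases, targets=["duloxetine"])
        s = compute_tto(an, "duloxetine", "Erectile dysfunction")
        assert s.n == 1 and s.exclusions["no_event_for_pt"] == 1

    def test_recovers_generator_onsets(self, analytic):
        s = compute_tto(analytic, "duloxetine", "Erectile dysfunction")
        assert s.n >= 3
        assert (s.days >= 1).all()
        n_cases = int((analytic.cases["drug"] == "duloxetine").sum())
        assert s.n + sum(s.exclusions.values()) == n_cases


class TestTtoSummary:
    def test_averaging_quartile_convention(self):
        out = tto_summary(np.array([1, 2, 3, 4, 5]))
        assert (out["median"], out["q1"], out["q3"]) == (3.0, 1.5, 4.5)

    def test_single_value(self):
        out = tto_summary(np.array([7]))
        assert out == {"n": 1, "median": 7.0, "q1": 7.0, "q3": 7.0, "min": 7.0, "max": 7.0}

    def test_half_integer_quartiles_representable_at_n17(self):
        # with n = 17 the quartile positions are 4.5 and 13.5, so integer-day
        # data can print half-integer quartiles
        days = np.array([2, 5, 10, 20, 21, 25, 30, 35, 38, 60, 90, 150, 200, 204, 400, 900, 1126])
        out = tto_summary(days)
        assert out["q1"] == 20.5
        assert out["median"] == 38.0
        assert out["q3"] == 202.0
        assert (out["min"], out["max"]) == (2.0, 1126.0)

    def test_order_statistics_monotone(self, rng):
        days = rng.integers(1, 1000, size=37)
        out = tto_summary(days)
        assert out["min"] <= out["q1"] <= out["median"] <= out["q3"] <= out["max"]

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            tto_summary(np.array([]))


class TestFitWeibull:
    def test_simulation_recovery(self, rng):
        for scale, shape in [(110.0, 0.65), (500.55, 0.49)]:
            t = scale * rng.weibull(shape, size=2000)
            fit = fit_weibull(t)
            assert fit.scale == pytest.approx(scale, rel=0.05)
            assert fit.shape == pytest.approx(shape, rel=0.05)
            assert fit.scale_lo95 < fit.scale < fit.scale_hi95
            assert fit.shape_lo95 < fit.shape < fit.shape_hi95

    def test_exponential_identity_with_constrained_shape(self, rng):
        t = rng.exponential(60.0, size=500)
        fit = fit_weibull(t, fixed_shape=1.0)
        assert fit.scale == pytest.approx(t.mean())

    def test_matches_scipy_mle(self, rng):
        t = 110.0 * rng.weibull(0.65, size=300)
        fit = fit_weibull(t)
        c, _, s = stats.weibull_min.fit(t, floc=0)
        assert fit.shape == pytest.approx(c, rel=1e-4)
        assert fit.scale == pytest.approx(s, rel=1e-4)

    def test_n3_fit_is_the_likelihood_maximum_by_grid_search(self):
        t = np.array([3.0, 17.0, 80.0])
        fit = fit_weibull(t)

        def loglik(scale, shape):
            return float(
                len(t) * (math.log(shape) - math.log(scale))
                + (shape - 1) * np.sum(np.log(t / scale))
                - np.sum((t / scale) ** shape)
            )

        best = max(
            (loglik(sc, sh), sc, sh)
            for sc in np.linspace(5, 200, 120)
            for sh in np.linspace(0.1, 4.0, 120)
        )
        assert loglik(fit.scale, fit.shape) >= best[0]
        assert np.isfinite([fit.shape_lo95, fit.shape_hi95]).all()

    def test_degenerate_sample_is_error(self):
        with pytest.raises(ValueError):
            fit_weibull(np.array([5.0, 5.0, 5.0]))

    def test_too_small_sample_is_error(self):
        with pytest.raises(ValueError):
            fit_weibull(np.array([1.0, 2.0]))


class TestClassifyFailure:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (0.42, 0.88, "early"),
            (0.40, 0.59, "early"),
            (0.9, 1.2, "random"),
            (1.05, 1.6, "wear_out"),
            (1.0, 1.0, "random"),  # boundary: CI touching 1 contains it
        ],
    )
    def test_rule_branches(self, lo, hi, expected):
        assert classify_failure((lo, hi)) == expected

    def test_exhaustive_and_exclusive_over_random_cis(self, rng):
        for _ in range(500):
            lo = rng.uniform(0.1, 2.0)
            hi = lo + rng.uniform(0.0, 1.5)
            assert classify_failure((lo, hi)) in ("early", "random", "wear_out")

    def test_fit_classification_integrates(self, rng):
        t = 110.0 * rng.weibull(0.65, size=500)
        assert fit_weibull(t).failure_type == "early"


class TestKmCurve:
    def test_readout_is_empirical_cdf(self):
        c = km_curve(np.array([10, 20, 30, 40]))
        assert c.at(30) == pytest.approx(0.75)
        assert c.at(5) == 0.0
        assert c.at(40) == pytest.approx(1.0)

    def test_printed_percentage_convention_n17(self):
        days = np.array([1, 2, 5, 10, 20, 29, 45, 60, 90, 120, 150, 200, 250, 300, 400, 500, 600])
        c = km_curve(days)
        assert round(100 * c.at(30), 2) == 35.29  # 6 of 17 within 30 days

    def test_equals_ecdf_exactly_without_censoring(self, rng):
        days = rng.integers(1, 300, size=200)
        c = km_curve(days)
        for t in [1, 10, 50, 150, 299]:
            assert c.at(t) == pytest.approx(np.mean(days <= t))

    def test_nondecreasing_and_reaches_one(self, rng):
        days = rng.integers(1, 50, size=77)
        c = km_curve(days)
        assert (np.diff(c.cumulative_incidence) >= 0).all()
        assert c.cumulative_incidence[-1] == pytest.approx(1.0)


class TestLogrank:
    def test_identical_samples_give_zero_statistic(self):
        stat, p = logrank_test(np.array([1, 2, 3]), np.array([1, 2, 3]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_order_invariance(self, rng):
        a = rng.integers(1, 100, size=30)
        b = rng.integers(1, 100, size=25)
        s1 = logrank_test(a, b)
        s2 = logrank_test(np.sort(a)[::-1], rng.permutation(b))
        assert s1 == pytest.approx(s2)

    def test_label_invariance(self, rng):
        a = 110.0 * rng.weibull(0.65, size=50)
        b = 500.0 * rng.weibull(0.49, size=60)
        assert logrank_test(a, b) == pytest.approx(logrank_test(b, a))

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            logrank_test(np.array([]), np.array([1.0]))

    def test_separated_groups_are_significant(self, rng):
        a = 10.0 * rng.weibull(1.0, size=100) + 1
        b = 500.0 * rng.weibull(1.0, size=100) + 1
        _, p = logrank_test(a, b)
        assert p < 1e-6
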