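"""Anchored trend fitting: OLS slopes, subject averaging, scenarios."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogtrend.errors import (
    AnchorMissingError,
    DegenerateDesignError,
    InconsistentPeriodError,
    InsufficientDataError,
    MissingDataError,
)
from cogtrend.fixtures import OPTIMISTIC, load_fixture
from cogtrend.standardization import StandardizedSeries
from cogtrend.trends import (
    PeriodSpec,
    TrendModel,
    average_subject_slopes,
    build_trend_model,
    fit_slope,
    scenario_slopes,
)


def brute_force_slope(points):
    """Independent closed-form oracle: cov(x, y) / var(x) by summation."""
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    xbar = sum(xs) / len(xs)
    ybar = sum(ys) / len(ys)
    num = sum((x - xbar) * (y - ybar) for x, y in points)
    den = sum((x - xbar) ** 2 for x in xs)
    return num / den


class TestFitSlope:
    def test_two_point_slope(self):
        assert fit_slope([(2000, 100.0), (2010, 101.0)]) == pytest.approx(0.1)

    def test_flat_series(self):
        pts = [(1992, 100.0), (2002, 100.0), (2012, 100.0)]
        assert fit_slope(pts) == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_oracle(self):
        pts = [(1990, 100.0), (2000, 102.0), (2010, 101.0)]
        assert fit_slope(pts) == pytest.approx(brute_force_slope(pts), abs=1e-10)

    @given(
        st.lists(
            st.tuples(st.integers(1970, 2020), st.floats(50, 150)),
            min_size=2,
            max_size=12,
            unique_by=lambda p: p[0],
        )
    )
    def test_oracle_agreement_on_random_instances(self, pts):
        assert fit_slope(pts) == pytest.approx(brute_force_slope(pts), abs=1e-10)

    @given(
        st.lists(
            st.tuples(st.integers(1970, 2020), st.floats(50, 150)),
            min_size=2,
            max_size=10,
            unique_by=lambda p: p[0],
        ),
        st.integers(-500, 500),
        st.floats(0.1, 20),
    )
    def test_year_shift_invariance_and_value_scale_equivariance(self, pts, dy, a):
        base = fit_slope(pts)
        shifted = fit_slope([(x + dy, y) for x, y in pts])
        scaled = fit_slope([(x, a * y) for x, y in pts])
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert scaled == pytest.approx(a * base, rel=1e-9, abs=1e-9)

    @given(
        slope=st.floats(-1, 1),
        intercept=st.floats(50, 150),
        years=st.lists(st.integers(1978, 2012), min_size=2, max_size=8, unique=True),
    )
    def test_noiseless_linear_series_recovered_exactly(self, slope, intercept, years):
        pts = [(y, intercept + slope * (y - 2000)) for y in years]
        assert fit_slope(pts) == pytest.approx(slope, abs=1e-8)

    def test_period_filter_is_inclusive(self):
        pts = [(1978, 100.0), (1990, 101.0), (2012, 103.0), (2020, 110.0)]
        period = PeriodSpec("w", 1978, 2012)
        assert fit_slope(pts, period) == pytest.approx(
            brute_force_slope(pts[:3]), abs=1e-10
        )

    def test_insufficient_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_slope([(2000, 100.0)])

    def test_zero_year_variance_rejected(self):
        with pytest.raises(DegenerateDesignError):
            fit_slope([(2000, 100.0), (2000, 101.0)])


class TestAverageSubjectSlopes:
    @pytest.mark.parametrize(
        "slopes, expected",
        [
            ({"math": 0.0914, "reading": 0.0016}, 0.0465),
            ({"math": 0.1186, "reading": 0.2150}, 0.1668),
        ],
    )
    def test_published_subject_averages(self, slopes, expected):
        # printed averages come from unrounded subject slopes, hence 5e-4
        assert average_subject_slopes(slopes) == pytest.approx(expected, abs=5e-4)

    @given(st.floats(-1, 1))
    def test_equal_slopes_fixed_point(self, m):
        assert average_subject_slopes({"math": m, "reading": m}) == pytest.approx(m)

    def test_empty_rejected(self):
        with pytest.raises(MissingDataError):
            average_subject_slopes({})


class TestBuildTrendModel:
    def test_anchor_is_observed_value_not_regression_intercept(self):
        series = StandardizedSeries(
            "White", [("2008", 2008, 102.29), ("2012", 2012, 102.28)]
        )
        model = build_trend_model(series, 0.0465, 2012)
        assert model.anchor_value == pytest.approx(102.28)
        assert model.predict(2012) == pytest.approx(102.28)

    @pytest.mark.parametrize(
        "anchor, slope, year, expected",
        [
            (102.28, 0.0465, 2060, 104.51),  # optimistic White at horizon
            (105.05, 0.1995, 2060, 114.62),  # pessimistic Asian at horizon
        ],
    )
    def test_horizon_predictions_match_published_cells(
        self, anchor, slope, year, expected
    ):
        model = TrendModel("g", slope, 2012, anchor)
        assert model.predict(year) == pytest.approx(expected, abs=0.01)

    def test_missing_anchor_year_rejected(self):
        series = StandardizedSeries("g", [("2008", 2008, 101.0)])
        with pytest.raises(AnchorMissingError):
            build_trend_model(series, 0.1, 2012)


class TestScenarioSlopes:
    @staticmethod
    def _models():
        slopes = {"W": 0.0465, "B": 0.1439, "H": 0.1539, "A": 0.1668}
        return [TrendModel(g, m, 2012, 100.0, "p") for g, m in slopes.items()]

    def test_best_assigns_maximum_to_all(self):
        out = scenario_slopes(self._models(), "best")
        assert set(out.values()) == {0.1668}

    def test_worst_assigns_minimum_to_all(self):
        out = scenario_slopes(self._models(), "worst")
        assert set(out.values()) == {0.0465}

    def test_single_group_degenerate(self):
        (model,) = self._models()[:1]
        for mode in ("best", "worst"):
            assert scenario_slopes([model], mode) == {"W": model.slope}

    def test_tie_break_follows_group_order(self):
        models = [
            TrendModel("a", 0.2, 2012, 100.0, "p"),
            TrendModel("b", 0.2, 2012, 100.0, "p"),
        ]
        assert scenario_slopes(models, "best", group_order=["b", "a"])["a"] == 0.2

    def test_mixed_periods_rejected(self):
        models = [
            TrendModel("a", 0.1, 2012, 100.0, "p1"),
            TrendModel("b", 0.2, 2012, 100.0, "p2"),
        ]
        with pytest.raises(InconsistentPeriodError):
            scenario_slopes(models, "best")


def test_combined_cohort_series_does_not_reproduce_published_average_slope():
    """Negative control for the fitting protocol.

    Fitting the combined White cohort series on cohort years ignores that
    each subject was surveyed in its own calendar year; the result (~0.07)
    must differ from the published per-subject-then-average slope 0.0465.
    """
    t1 = load_fixture("table1_standardized").payload
    cohort_years = [1978, 1982, 1986, 1990, 1992, 1994, 1996, 1999, 2004, 2008, 2012]
    combined = fit_slope(list(zip(cohort_years, t1["White"])))
    assert abs(combined - 0.0465) > 0.01
    assert combined == pytest.approx(0.07, abs=0.005)
    # while the per-subject-then-average protocol is what matches:
    published = load_fixture("table2_slopes").payload
    row = published[
        (published["subject"] == "Average") & (published["period"] == OPTIMISTIC)
    ]
    assert float(row.iloc[0]["White"]) == pytest.approx(
        np.mean([0.0914, 0.0016]), abs=5e-4
    )
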