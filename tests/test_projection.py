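"""Share interpolation, weighted means and scenario projection."""

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogtrend.errors import (
    EmptyPopulationError,
    ExtrapolationError,
    InvalidHorizonError,
)
from cogtrend.fixtures import GROUPS, PROJECTION_YEARS
from cogtrend.projection import (
    POPULATION,
    ShareTable,
    group_gap,
    interpolate_shares,
    per_decade_rate,
    project,
    weighted_population_mean,
)
from cogtrend.trends import TrendModel


def small_table():
    rows = []
    for year, (pa, pb) in {2010: (0.40, 0.50), 2020: (0.42, 0.48)}.items():
        rows += [
            {"year": year, "group": "a", "proportion": pa},
            {"year": year, "group": "b", "proportion": pb},
        ]
    return ShareTable(pd.DataFrame(rows))


class TestShareTable:
    def test_tabulated_census_row_returned_exactly(self, share_table):
        got = interpolate_shares(share_table, 2060)
        assert got == pytest.approx(
            {"White": 0.4258, "Black": 0.1316, "Hispanic": 0.3064, "Asian": 0.0788}
        )

    def test_midpoint_interpolation(self):
        got = small_table().at(2015)
        assert got["a"] == pytest.approx(0.41)
        assert got["b"] == pytest.approx(0.49)

    def test_interpolation_weights_are_linear(self, share_table):
        # 2013 sits one third of the way from the 2012 row to the 2015 row
        got = share_table.at(2013)
        expected = 0.6298 + (0.6175 - 0.6298) / 3
        assert got["White"] == pytest.approx(expected, abs=1e-12)

    def test_extrapolation_rejected(self, share_table):
        with pytest.raises(ExtrapolationError):
            share_table.at(2061)
        with pytest.raises(ExtrapolationError):
            share_table.at(2011)

    def test_share_sum_above_one_rejected(self):
        bad = pd.DataFrame(
            [
                {"year": 2000, "group": "a", "proportion": 0.7},
                {"year": 2000, "group": "b", "proportion": 0.4},
            ]
        )
        with pytest.raises(ValueError):
            ShareTable(bad)

    def test_renormalized_shares_sum_to_one(self, share_table):
        for year in (2012, 2033, 2060):
            assert sum(share_table.renormalized_at(year).values()) == pytest.approx(
                1.0, abs=1e-12
            )


class TestWeightedPopulationMean:
    def test_anchor_year_population_matches_published(self, share_table):
        values = {"White": 102.28, "Black": 91.14, "Hispanic": 93.60, "Asian": 105.05}
        got = weighted_population_mean(values, share_table.at(2012))
        assert got == pytest.approx(99.50, abs=0.01)

    def test_horizon_population_matches_published(self, share_table):
        slopes = {"White": 0.0465, "Black": 0.1439, "Hispanic": 0.1539, "Asian": 0.1668}
        anchors = {"White": 102.28, "Black": 91.14, "Hispanic": 93.60, "Asian": 105.05}
        values = {g: anchors[g] + 48 * slopes[g] for g in anchors}
        got = weighted_population_mean(values, share_table.at(2060))
        assert got == pytest.approx(103.17, abs=0.01)

    @given(st.floats(60, 140), st.floats(0.01, 0.5), st.floats(0.01, 0.5))
    def test_constant_field_is_share_independent(self, v, pa, pb):
        got = weighted_population_mean({"a": v, "b": v}, {"a": pa, "b": pb})
        assert got == pytest.approx(v)

    def test_zero_share_sum_rejected(self):
        with pytest.raises(EmptyPopulationError):
            weighted_population_mean({"a": 100.0}, {"a": 0.0})

    def test_group_mismatch_rejected(self):
        with pytest.raises(KeyError):
            weighted_population_mean({"a": 100.0}, {"b": 0.5})

    def test_unrenormalized_mode_is_plain_dot_product(self):
        got = weighted_population_mean(
            {"a": 100.0, "b": 90.0}, {"a": 0.5, "b": 0.25}, renormalize=False
        )
        assert got == pytest.approx(100 * 0.5 + 90 * 0.25)


class TestProject:
    def test_pessimistic_standard_2030_population(
        self, pessimistic_models, share_table
    ):
        result = project(pessimistic_models, share_table, [2030])
        assert result.at(2030) == pytest.approx(100.04, abs=0.01)
        assert result.at(2030, "Asian") == pytest.approx(108.64, abs=0.01)

    def test_optimistic_worst_case_2060_population(
        self, optimistic_models, share_table
    ):
        result = project(
            optimistic_models, share_table, [2060], scenario="worst",
            group_order=GROUPS,
        )
        assert result.at(2060) == pytest.approx(100.36, abs=0.01)

    def test_anchor_year_identical_across_scenarios(
        self, optimistic_models, share_table
    ):
        for scenario in ("standard", "best", "worst"):
            result = project(
                optimistic_models, share_table, [2012], scenario, group_order=GROUPS
            )
            assert result.at(2012) == pytest.approx(99.50, abs=0.01)

    def test_population_is_convex_combination_each_year(
        self, optimistic_models, share_table
    ):
        result = project(optimistic_models, share_table, PROJECTION_YEARS)
        for year, by_group in result.values.items():
            group_vals = [by_group[g] for g in GROUPS]
            assert min(group_vals) <= by_group[POPULATION] <= max(group_vals)

    def test_scenario_ordering_after_anchor_year(
        self, optimistic_models, share_table
    ):
        results = {
            s: project(
                optimistic_models, share_table, PROJECTION_YEARS, s,
                group_order=GROUPS,
            )
            for s in ("standard", "best", "worst")
        }
        for year in PROJECTION_YEARS:
            if year == 2012:
                continue
            assert (
                results["best"].at(year)
                >= results["standard"].at(year)
                >= results["worst"].at(year)
            )

    def test_group_trajectories_exactly_linear(
        self, optimistic_models, share_table
    ):
        result = project(optimistic_models, share_table, [2020, 2040, 2060])
        for g, model in optimistic_models.items():
            v20, v40, v60 = (result.at(y, g) for y in (2020, 2040, 2060))
            assert v40 - v20 == pytest.approx(20 * model.slope, abs=1e-12)
            assert v60 - v40 == pytest.approx(20 * model.slope, abs=1e-12)

    def test_grid_year_weighting_matches_hand_computation(
        self, optimistic_models, share_table
    ):
        result = project(optimistic_models, share_table, [2040])
        p = share_table.at(2040)
        v = {g: m.predict(2040) for g, m in optimistic_models.items()}
        expected = sum(p[g] * v[g] for g in v) / sum(p.values())
        assert result.at(2040) == pytest.approx(expected, abs=1e-12)


class TestGapAndRates:
    def test_published_2060_gaps(
        self, optimistic_models, pessimistic_models, share_table
    ):
        opt = project(optimistic_models, share_table, [2060])
        pes = project(pessimistic_models, share_table, [2060])
        assert group_gap(opt, 2060, "White", "Hispanic") == pytest.approx(3.5, abs=0.05)
        assert group_gap(pes, 2060, "Asian", "White") == pytest.approx(12.1, abs=0.05)

    def test_gap_with_self_is_zero(self, optimistic_models, share_table):
        result = project(optimistic_models, share_table, [2040])
        assert group_gap(result, 2040, "White", "White") == 0.0

    def test_unknown_group_rejected(self, optimistic_models, share_table):
        result = project(optimistic_models, share_table, [2040])
        with pytest.raises(KeyError):
            group_gap(result, 2040, "White", "Martian")

    @pytest.mark.parametrize(
        "total, horizon, expected",
        [(2.16, 48, 0.45), (3.68, 48, 0.77), (0.0, 30, 0.0)],
    )
    def test_per_decade_rate(self, total, horizon, expected):
        assert per_decade_rate(total, horizon) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_horizon_rejected(self):
        with pytest.raises(InvalidHorizonError):
            per_decade_rate(1.0, 0)


def test_projection_frame_round_trips_through_csv(
    optimistic_models, share_table, tmp_path
):
    result = project(optimistic_models, share_table, [2012, 2040, 2060])
    path = tmp_path / "projection.csv"
    frame = result.to_frame()
    frame.to_csv(path, index=False)
    back = pd.read_csv(path)
    pd.testing.assert_frame_equal(frame, back)


def test_mixed_anchor_models_rejected(share_table):
    from cogtrend.errors import InconsistentPeriodError

    models = {
        "White": TrendModel("White", 0.1, 2012, 100.0, "p"),
        "Black": TrendModel("Black", 0.1, 2010, 95.0, "p"),
    }
    with pytest.raises(InconsistentPeriodError):
        project(models, share_table, [2040])
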