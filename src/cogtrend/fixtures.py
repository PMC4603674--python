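"""Packaged reference tables from the motivating study.

Four input tables ship with the package at full printed precision:

* ``table1_standardized`` — combined-cohort standardized scores per group,
  1978/80 through 2012 (the raw scale summaries behind them are not
  published, so this table is consumed as an input downstream);
* ``table2_slopes`` — per-subject and subject-averaged OLS slopes for the
  two fitting periods;
* ``table3_student_shares`` — survey participant percentages per group;
* ``table4_census_shares`` — census population-share projections
  2012-2060.

Share tables are stored as percentages exactly as printed and converted
to fractions on load.  The published projection/effect tables (5-10) are
packaged separately as *golden* tables for regression comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .errors import UnknownFixtureError
from .projection import ShareTable
from .trends import PeriodSpec, TrendModel

__all__ = [
    "Fixture",
    "load_fixture",
    "load_golden",
    "FIXTURE_NAMES",
    "GOLDEN_NAMES",
    "GROUPS",
    "OPTIMISTIC",
    "PESSIMISTIC",
    "PERIODS",
    "PROJECTION_YEARS",
    "ANCHOR_YEAR",
    "BASELINE_GROUP",
    "paper_share_table",
    "paper_average_slopes",
    "paper_anchor_values",
    "paper_models",
]

GROUPS = ("White", "Black", "Hispanic", "Asian")
#: fitting-period labels: the long window is the optimistic one
OPTIMISTIC = "1978/80-2012"
PESSIMISTIC = "1992-2012"
PERIODS = {
    OPTIMISTIC: PeriodSpec(OPTIMISTIC, 1978, 2012),
    PESSIMISTIC: PeriodSpec(PESSIMISTIC, 1992, 2012),
}
PROJECTION_YEARS = (2012, 2015, 2020, 2025, 2030, 2035, 2040, 2045, 2050, 2055, 2060)
ANCHOR_YEAR = 2012
BASELINE_GROUP = "White"

FIXTURE_NAMES = (
    "table1_standardized",
    "table2_slopes",
    "table3_student_shares",
    "table4_census_shares",
)
GOLDEN_NAMES = (
    "table5_projection_optimistic",
    "table6_projection_pessimistic",
    "table7_effects_optimistic",
    "table8_effects_pessimistic",
    "table9_scenarios_optimistic",
    "table10_scenarios_pessimistic",
)

_PERCENT_TABLES = {"table3_student_shares", "table4_census_shares"}


@dataclass(frozen=True)
class Fixture:
    """A named packaged table with its parsed payload."""

    name: str
    payload: pd.DataFrame


def _read_packaged(relpath: str) -> pd.DataFrame:
    ref = resources.files("cogtrend").joinpath("data", relpath)
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_fixture(name: str) -> Fixture:
    """Load one packaged input table by name.

    Percentage tables are converted to fractions; everything else is
    returned at full printed precision.
    """
    if name not in FIXTURE_NAMES:
        raise UnknownFixtureError(
            f"unknown fixture {name!r}; available: {FIXTURE_NAMES}"
        )
    frame = _read_packaged(f"{name}.csv")
    if name in _PERCENT_TABLES:
        for col in list(GROUPS) + ["Sum"]:
            frame[col] = frame[col] / 100.0
    return Fixture(name, frame)


def load_golden(name: str) -> pd.DataFrame:
    """Load one published output table (for comparison, never as input)."""
    if name not in GOLDEN_NAMES:
        raise UnknownFixtureError(
            f"unknown golden table {name!r}; available: {GOLDEN_NAMES}"
        )
    return _read_packaged(f"golden/{name}.csv")


def paper_share_table() -> ShareTable:
    """Census share projections as a :class:`ShareTable` (fractions)."""
    wide = load_fixture("table4_census_shares").payload
    return ShareTable.from_wide(wide[["year", *GROUPS]])


def paper_average_slopes(period: str) -> dict[str, float]:
    """Subject-averaged slopes for one fitting period, as printed."""
    t2 = load_fixture("table2_slopes").payload
    row = t2[(t2["subject"] == "Average") & (t2["period"] == period)]
    if row.empty:
        raise UnknownFixtureError(f"no Average slope row for period {period!r}")
    return {g: float(row.iloc[0][g]) for g in GROUPS}


def paper_anchor_values(anchor_year: int = ANCHOR_YEAR) -> dict[str, float]:
    """Standardized anchor levels: the combined-cohort row at ``anchor_year``."""
    t1 = load_fixture("table1_standardized").payload
    row = t1[t1["cohort"] == str(anchor_year)]
    if row.empty:
        raise UnknownFixtureError(f"no cohort row for anchor year {anchor_year}")
    return {g: float(row.iloc[0][g]) for g in GROUPS}


def paper_models(period: str, anchor_year: int = ANCHOR_YEAR) -> dict[str, TrendModel]:
    """Anchored trend models built from the packaged input tables."""
    slopes = paper_average_slopes(period)
    anchors = paper_anchor_values(anchor_year)
    return {
        g: TrendModel(g, slopes[g], anchor_year, anchors[g], period)
        for g in GROUPS
    }
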