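"""Population-weighted projection of group trajectories.

Group trajectories are exactly linear (anchored trend models); the
population trajectory is their share-weighted mean and bends with the
composition path.  Shares over the modeled groups may sum to less than
one when small groups are excluded, so weighting renormalizes by the
per-year share sum by default — only then is the population value a
convex combination of the group values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyPopulationError,
    ExtrapolationError,
    InconsistentPeriodError,
    InvalidHorizonError,
)
from .trends import TrendModel, scenario_slopes

__all__ = [
    "ShareTable",
    "ProjectionResult",
    "POPULATION",
    "interpolate_shares",
    "weighted_population_mean",
    "project",
    "group_gap",
    "per_decade_rate",
]

#: key under which the weighted total is stored in projection results
POPULATION = "population"

Scenario = Literal["standard", "best", "worst"]


class ShareTable:
    """Year x group population proportions (fractions, not percentages).

    Per-year sums over the modeled groups may be below 1; they must never
    exceed it.  Years between tabulated rows are linearly interpolated.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"year", "group", "proportion"}
        if not required.issubset(frame.columns):
            raise ValueError(f"share table needs columns {sorted(required)}")
        f = frame[["year", "group", "proportion"]].copy()
        f["year"] = f["year"].astype(int)
        if ((f["proportion"] < 0) | (f["proportion"] > 1)).any():
            raise ValueError("proportions must lie in [0, 1]")
        sums = f.groupby("year")["proportion"].sum()
        if (sums > 1 + 1e-9).any():
            bad = sums[sums > 1 + 1e-9].index.tolist()
            raise ValueError(f"share sums exceed 1 in year(s) {bad}")
        self._wide = f.pivot(index="year", columns="group", values="proportion")
        self._wide = self._wide.sort_index()
        if self._wide.isna().any().any():
            raise ValueError("every group needs a share in every tabulated year")

    @classmethod
    def from_csv(cls, path, percent: bool = False) -> "ShareTable":
        """Read a ``year,group,proportion`` CSV; ``percent`` divides by 100."""
        f = pd.read_csv(path)
        if percent:
            f["proportion"] = f["proportion"] / 100.0
        return cls(f)

    @classmethod
    def from_wide(cls, frame: pd.DataFrame, percent: bool = False) -> "ShareTable":
        """Build from a wide year x group table (e.g. a census print-out)."""
        long = frame.melt(id_vars="year", var_name="group", value_name="proportion")
        if percent:
            long["proportion"] = long["proportion"] / 100.0
        return cls(long)

    @property
    def groups(self) -> list[str]:
        return [str(g) for g in self._wide.columns]

    @property
    def years(self) -> list[int]:
        return [int(y) for y in self._wide.index]

    def to_frame(self) -> pd.DataFrame:
        long = self._wide.reset_index().melt(
            id_vars="year", var_name="group", value_name="proportion"
        )
        return long.sort_values(["year", "group"], ignore_index=True)

    def at(self, year: int | float) -> dict[str, float]:
        """Shares at ``year``: exact row, else per-group linear interpolation."""
        return interpolate_shares(self, year)

    def renormalized_at(self, year: int | float) -> dict[str, float]:
        """Shares at ``year`` rescaled to sum to one over the modeled groups."""
        raw = self.at(year)
        total = sum(raw.values())
        if total <= 0:
            raise EmptyPopulationError(f"share sum is zero at year {year}")
        return {g: p / total for g, p in raw.items()}


def interpolate_shares(table: ShareTable, year: int | float) -> dict[str, float]:
    """Group shares at ``year`` by per-group linear interpolation.

    Years outside the tabulated range raise :class:`ExtrapolationError`;
    shares are never silently extrapolated.
    """
    wide = table._wide
    years = wide.index.to_numpy()
    if year < years[0] or year > years[-1]:
        raise ExtrapolationError(
            f"year {year} outside share table range [{years[0]}, {years[-1]}]"
        )
    if year in wide.index:
        row = wide.loc[year]
        return {str(g): float(v) for g, v in row.items()}
    return {
        str(g): float(np.interp(year, years, wide[g].to_numpy()))
        for g in wide.columns
    }


def weighted_population_mean(
    group_values: Mapping[str, float],
    shares: Mapping[str, float],
    renormalize: bool = True,
) -> float:
    """Share-weighted mean of group values.

    With ``renormalize`` (default) the weights are divided by their sum,
    so the result is a convex combination even when the modeled groups
    cover less than the full population.
    """
    if set(group_values) != set(shares):
        raise KeyError(
            f"group mismatch: values {sorted(group_values)} vs shares "
            f"{sorted(shares)}"
        )
    total = sum(shares.values())
    if total <= 0:
        raise EmptyPopulationError("population shares sum to zero")
    acc = sum(shares[g] * group_values[g] for g in group_values)
    return acc / total if renormalize else acc


@dataclass
class ProjectionResult:
    """Projected levels by year: each group plus the weighted total."""

    scenario: Scenario
    period: str
    values: dict[int, dict[str, float]] = field(default_factory=dict)

    def at(self, year: int, group: str = POPULATION) -> float:
        return self.values[year][group]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "scenario": self.scenario,
                "period": self.period,
                "year": year,
                "group": group,
                "value": value,
            }
            for year, by_group in sorted(self.values.items())
            for group, value in by_group.items()
        ]
        return pd.DataFrame(rows)

    def total_change(self, end_year: int, start_year: int) -> float:
        """Population change between two years, from unrounded levels."""
        return self.at(end_year) - self.at(start_year)


def project(
    models: Mapping[str, TrendModel],
    shares: ShareTable,
    years: Sequence[int],
    scenario: Scenario = "standard",
    renormalize: bool = True,
    group_order: Sequence[str] | None = None,
) -> ProjectionResult:
    """Project each group and the population total over ``years``.

    Under ``best``/``worst`` scenarios every group's own slope is replaced
    by the maximum/minimum slope across groups; anchors are untouched.
    """
    model_list = list(models.values())
    anchor_years = {m.anchor_year for m in model_list}
    periods = {m.period for m in model_list}
    if len(anchor_years) > 1 or len(periods) > 1:
        raise InconsistentPeriodError(
            "models must share one anchor year and fitting period"
        )
    if scenario == "standard":
        slope_used = {g: m.slope for g, m in models.items()}
    else:
        slope_used = scenario_slopes(model_list, scenario, group_order)
    result = ProjectionResult(scenario=scenario, period=model_list[0].period)
    for year in years:
        by_group = {
            g: m.predict(year, slope=slope_used[g]) for g, m in models.items()
        }
        share_map = {g: shares.at(year)[g] for g in models}
        by_group[POPULATION] = weighted_population_mean(
            {g: by_group[g] for g in models}, share_map, renormalize=renormalize
        )
        result.values[int(year)] = by_group
    return result


def group_gap(
    result: ProjectionResult, year: int, group_a: str, group_b: str
) -> float:
    """Projected level difference ``group_a - group_b`` at ``year``."""
    by_group = result.values[year]
    for g in (group_a, group_b):
        if g not in by_group:
            raise KeyError(f"unknown group {g!r} in projection result")
    return by_group[group_a] - by_group[group_b]


def per_decade_rate(total_change: float, horizon_years: float) -> float:
    """Average change per decade over a horizon of ``horizon_years``."""
    if horizon_years <= 0:
        raise InvalidHorizonError(
            f"horizon must be positive, got {horizon_years}"
        )
    return total_change / (horizon_years / 10.0)
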