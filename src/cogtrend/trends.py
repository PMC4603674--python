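"""Anchored linear trend estimation per demographic group.

Slopes are fit by ordinary least squares per subject on that subject's own
survey years, then averaged across subjects.  The trajectory intercept is
NOT the regression intercept: the trend is anchored at the last observed
value, so predictions read

    value(year) = anchor_value + slope * (year - anchor_year)

Best/worst scenario variants substitute the maximum/minimum group slope
for every group.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    AnchorMissingError,
    DegenerateDesignError,
    InconsistentPeriodError,
    InsufficientDataError,
    MissingDataError,
)
from .standardization import StandardizedSeries

__all__ = [
    "PeriodSpec",
    "TrendModel",
    "fit_slope",
    "average_subject_slopes",
    "build_trend_model",
    "scenario_slopes",
    "fit_group_slopes",
]


@dataclass(frozen=True)
class PeriodSpec:
    """Inclusive fitting window on the calendar axis."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.start_year >= self.end_year:
            raise ValueError(
                f"start_year must precede end_year in period {self.label!r}"
            )

    def contains(self, year: int) -> bool:
        return self.start_year <= year <= self.end_year


@dataclass(frozen=True)
class TrendModel:
    """Anchored linear trajectory for one group.

    ``slope`` is in standardized points per calendar year; ``anchor_value``
    is the observed (not fitted) level at ``anchor_year``.
    """

    group: str
    slope: float
    anchor_year: int
    anchor_value: float
    period: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or not np.isfinite(self.anchor_value):
            raise ValueError("slope and anchor_value must be finite")

    def predict(self, year: int | float, slope: float | None = None) -> float:
        """Level at ``year``; an override ``slope`` serves scenario runs."""
        m = self.slope if slope is None else slope
        return self.anchor_value + m * (year - self.anchor_year)


def fit_slope(
    points: Sequence[tuple[float, float]],
    period: PeriodSpec | None = None,
) -> float:
    """OLS slope of value on calendar year over points inside ``period``.

    Each subject's own survey years must be used as x-values upstream;
    this function is agnostic about where the points came from.
    """
    if period is not None:
        points = [(x, y) for x, y in points if period.contains(int(x))]
    if len(points) < 2:
        raise InsufficientDataError(
            f"need >= 2 points to fit a slope, got {len(points)}"
        )
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all points share one calendar year")
    return float(stats.linregress(x, y).slope)


def average_subject_slopes(slopes: Mapping[str, float]) -> float:
    """Arithmetic mean of per-subject slopes.

    Averaging fitted slopes is NOT the same as fitting the averaged series
    when subjects are surveyed in different calendar years, which is the
    normal case here.
    """
    if not slopes:
        raise MissingDataError("no subject slopes to average")
    return sum(slopes.values()) / len(slopes)


def build_trend_model(
    series: StandardizedSeries,
    slope: float,
    anchor_year: int = 2012,
    period: str = "",
) -> TrendModel:
    """Anchor a fitted slope at the series' observed ``anchor_year`` value."""
    try:
        anchor_value = series.value_at(anchor_year)
    except KeyError as exc:
        raise AnchorMissingError(
            f"group {series.group!r} has no observation at {anchor_year}"
        ) from exc
    return TrendModel(series.group, slope, anchor_year, anchor_value, period)


def scenario_slopes(
    models: Sequence[TrendModel],
    mode: Literal["best", "worst"],
    group_order: Sequence[str] | None = None,
) -> dict[str, float]:
    """Assign every group the max (best) or min (worst) slope across groups.

    Ties on the extreme slope are broken by ``group_order`` (first listed
    wins), defaulting to the order the models were given in.
    """
    if not models:
        raise MissingDataError("no trend models supplied")
    periods = {m.period for m in models}
    if len(periods) > 1:
        raise InconsistentPeriodError(f"mixed fitting periods: {sorted(periods)}")
    if mode not in ("best", "worst"):
        raise ValueError(f"mode must be 'best' or 'worst', got {mode!r}")
    order = list(group_order) if group_order else [m.group for m in models]
    rank = {g: i for i, g in enumerate(order)}
    key = max if mode == "best" else min
    extreme = key(m.slope for m in models)
    # deterministic tie-break: among groups attaining the extreme, first in order
    chosen = min(
        (m for m in models if m.slope == extreme),
        key=lambda m: rank.get(m.group, len(rank)),
    )
    return {m.group: chosen.slope for m in models}


def fit_group_slopes(
    standardized,
    period: PeriodSpec,
) -> dict[str, dict[str, float]]:
    """Per-group per-subject OLS slopes over ``period``.

    ``standardized`` is the tidy frame from
    :func:`cogtrend.standardization.standardize_observations`.  Returns
    ``{group: {subject: slope, "average": mean}}``.
    """
    out: dict[str, dict[str, float]] = {}
    for (group, subject), gdf in standardized.groupby(["group", "subject"]):
        pts = list(zip(gdf["year"], gdf["value"]))
        out.setdefault(str(group), {})[str(subject)] = fit_slope(pts, period)
    for group, subj_slopes in out.items():
        subj_slopes["average"] = average_subject_slopes(subj_slopes)
    return out
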