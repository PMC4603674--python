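"""Exact four-term decomposition of projected population change.

The population-level change between the anchor year y0 and a horizon year
y splits exactly into

    e_base  = (y - y0) * m_base                         baseline-group trend
    e_minor = (y - y0) * sum_r p_{y0,r} (m_r - m_base)  minority catch-up
    e_pop   = sum_r v_{y0,r} (p_{y,r} - p_{y0,r})       composition change
    e_pm    = (y - y0) * sum_r (p_{y,r} - p_{y0,r}) (m_r - m_base)  interaction

with renormalized shares p, anchor levels v and per-year slopes m.  The
identity e_base + e_minor + e_pop + e_pm = population(y) - population(y0)
is algebraic and holds for arbitrary slopes and share paths — but only
when the shares form a proper convex combination, hence the
renormalization.  Note the catch-up term uses *anchor-year* shares; the
share drift acting on the slope differentials is carried entirely by the
interaction term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError, InconsistentPeriodError
from .projection import ShareTable
from .trends import TrendModel

__all__ = [
    "EffectDecomposition",
    "EconomicParams",
    "decompose",
    "decompose_series",
    "economic_gain",
]


@dataclass(frozen=True)
class EffectDecomposition:
    """The four effect components and their total for one horizon year."""

    year: int
    e_base: float
    e_minor: float
    e_pop: float
    e_pm: float
    e_total: float
    period: str = ""
    baseline_group: str = ""
    baseline_year: int = 2012

    def components(self) -> dict[str, float]:
        return {
            "e_base": self.e_base,
            "e_minor": self.e_minor,
            "e_pop": self.e_pop,
            "e_pm": self.e_pm,
            "e_total": self.e_total,
        }

    def per_decade(self, horizon_years: float | None = None) -> dict[str, float]:
        """Each component divided by the decades elapsed."""
        h = (self.year - self.baseline_year) if horizon_years is None else horizon_years
        return {k: v / (h / 10.0) for k, v in self.components().items()}


@dataclass(frozen=True)
class EconomicParams:
    """Per-capita productivity value of one standardized point per year.

    The default $810 is in purchasing-power-parity dollars at constant
    prices; no inflation or baseline growth is layered on top.
    """

    dollars_per_point: float = 810.0


def decompose(
    models: Mapping[str, TrendModel],
    shares: ShareTable,
    year: int,
    baseline_group: str,
) -> EffectDecomposition:
    """Split the projected population change at ``year`` into four effects.

    ``baseline_group`` supplies the reference slope m_base (conventionally
    the largest group); its anchor year is the baseline year y0.  Shares
    are renormalized over the modeled groups before any arithmetic so the
    additivity identity holds exactly.
    """
    if baseline_group not in models:
        raise ConfigurationError(
            f"baseline group {baseline_group!r} not among models "
            f"{sorted(models)}"
        )
    anchor_years = {m.anchor_year for m in models.values()}
    periods = {m.period for m in models.values()}
    if len(anchor_years) > 1 or len(periods) > 1:
        raise InconsistentPeriodError(
            "models must share one anchor year and fitting period"
        )
    y0 = models[baseline_group].anchor_year
    dt = year - y0
    p0 = shares.renormalized_at(y0)
    p1 = shares.renormalized_at(year)
    m_base = models[baseline_group].slope

    e_base = dt * m_base
    e_minor = dt * sum(
        p0[g] * (m.slope - m_base) for g, m in models.items()
    )
    e_pop = sum(
        m.anchor_value * (p1[g] - p0[g]) for g, m in models.items()
    )
    e_pm = dt * sum(
        (p1[g] - p0[g]) * (m.slope - m_base) for g, m in models.items()
    )
    return EffectDecomposition(
        year=int(year),
        e_base=e_base,
        e_minor=e_minor,
        e_pop=e_pop,
        e_pm=e_pm,
        e_total=e_base + e_minor + e_pop + e_pm,
        period=models[baseline_group].period,
        baseline_group=baseline_group,
        baseline_year=y0,
    )


def decompose_series(
    models: Mapping[str, TrendModel],
    shares: ShareTable,
    years: Sequence[int],
    baseline_group: str,
) -> pd.DataFrame:
    """Decomposition over several horizon years as a tidy frame."""
    rows = []
    for year in years:
        d = decompose(models, shares, year, baseline_group)
        rows.append({"period": d.period, "year": d.year, **d.components()})
    return pd.DataFrame(rows)


def economic_gain(delta: float, params: EconomicParams = EconomicParams()) -> int:
    """Per-capita yearly productivity value of a standardized-point change.

    Linear in ``delta`` and reported in whole currency units (half-up),
    at constant prices.
    """
    from ._rounding import round_half_up

    return int(round_half_up(delta * params.dollars_per_point, 0))
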