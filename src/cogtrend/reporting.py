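"""Full-analysis reproduction, golden comparison, and report plots.

`reproduce_study` regenerates every published projection and effect
table from the packaged input tables (standardized anchors, slopes,
census shares), writes them as CSV, and compares each cell against the
packaged golden tables at +/-0.01 after half-up rounding to the printed
precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from ._rounding import round_half_up
from .decomposition import EconomicParams, decompose, economic_gain
from .fixtures import (
    ANCHOR_YEAR,
    BASELINE_GROUP,
    GROUPS,
    OPTIMISTIC,
    PESSIMISTIC,
    PROJECTION_YEARS,
    load_golden,
    paper_models,
    paper_share_table,
)
from .projection import POPULATION, group_gap, per_decade_rate, project

logger = logging.getLogger(__name__)

__all__ = [
    "projection_table",
    "scenario_table",
    "effects_table",
    "gap_summary",
    "economic_summary",
    "reproduce_study",
    "write_report",
    "ReproductionReport",
]

_SCENARIOS = ("standard", "best", "worst")
_SCENARIO_COLUMNS = {"standard": "Standard", "best": "Best Case", "worst": "Worst Case"}
_HORIZON = PROJECTION_YEARS[-1] - ANCHOR_YEAR  # 48 years


def projection_table(period: str, scenario: str = "standard") -> pd.DataFrame:
    """Per-group and population projections, rounded as printed."""
    models = paper_models(period)
    shares = paper_share_table()
    result = project(models, shares, PROJECTION_YEARS, scenario, group_order=GROUPS)
    rows = []
    for year in PROJECTION_YEARS:
        row = {"year": year}
        for g in GROUPS:
            row[g] = round_half_up(result.at(year, g), 2)
        row["Population"] = round_half_up(result.at(year, POPULATION), 2)
        rows.append(row)
    return pd.DataFrame(rows)


def scenario_table(period: str) -> pd.DataFrame:
    """Population trajectory under standard/best/worst slope scenarios.

    The ``Total increase`` row is computed from unrounded endpoint levels.
    """
    models = paper_models(period)
    shares = paper_share_table()
    columns: dict[str, list] = {"year": [str(y) for y in PROJECTION_YEARS]}
    for scenario in _SCENARIOS:
        result = project(
            models, shares, PROJECTION_YEARS, scenario, group_order=GROUPS
        )
        col = [round_half_up(result.at(y, POPULATION), 2) for y in PROJECTION_YEARS]
        total = result.total_change(PROJECTION_YEARS[-1], ANCHOR_YEAR)
        col.append(round_half_up(total, 2))
        columns[_SCENARIO_COLUMNS[scenario]] = col
    columns["year"].append("Total increase")
    return pd.DataFrame(columns)[["year", *_SCENARIO_COLUMNS.values()]]


def effects_table(period: str) -> pd.DataFrame:
    """Four-term decomposition by horizon year plus a per-decade row."""
    models = paper_models(period)
    shares = paper_share_table()
    horizon_years = [y for y in PROJECTION_YEARS if y > ANCHOR_YEAR]
    rows = []
    for year in horizon_years:
        d = decompose(models, shares, year, BASELINE_GROUP)
        rows.append(
            {"year": str(year), **{k: round_half_up(v, 2) for k, v in d.components().items()}}
        )
    final = decompose(models, shares, horizon_years[-1], BASELINE_GROUP)
    rows.append(
        {
            "year": "per decade",
            **{k: round_half_up(v, 2) for k, v in final.per_decade().items()},
        }
    )
    return pd.DataFrame(rows)


def gap_summary() -> pd.DataFrame:
    """Current and projected 2060 group gaps under both fitting periods."""
    shares = paper_share_table()
    rows = []
    for a, b in (("White", "Black"), ("White", "Hispanic"), ("Asian", "White")):
        row = {"gap": f"{a}-{b}"}
        for period, tag in ((OPTIMISTIC, "optimistic"), (PESSIMISTIC, "pessimistic")):
            result = project(
                paper_models(period), shares, PROJECTION_YEARS, "standard"
            )
            row["2012"] = round_half_up(group_gap(result, ANCHOR_YEAR, a, b), 1)
            row[f"2060_{tag}"] = round_half_up(group_gap(result, 2060, a, b), 1)
        rows.append(row)
    return pd.DataFrame(rows)


def per_decade_summary() -> dict[str, float]:
    """Average population rise per decade for both fitting periods."""
    shares = paper_share_table()
    out = {}
    for period, tag in ((OPTIMISTIC, "optimistic"), (PESSIMISTIC, "pessimistic")):
        result = project(paper_models(period), shares, PROJECTION_YEARS, "standard")
        total = result.total_change(2060, ANCHOR_YEAR)
        out[tag] = round_half_up(per_decade_rate(total, _HORIZON), 2)
    return out


def economic_summary(
    params: EconomicParams = EconomicParams(),
) -> pd.DataFrame:
    """Dollar value of each 2060 effect component, both periods.

    Dollar figures are computed from the components as printed (rounded
    to 2 decimals), matching the published reporting path.  Constant
    prices; no baseline economic growth is modeled.
    """
    shares = paper_share_table()
    rows = []
    for period, tag in ((OPTIMISTIC, "optimistic"), (PESSIMISTIC, "pessimistic")):
        d = decompose(paper_models(period), shares, 2060, BASELINE_GROUP)
        row = {"period": tag}
        for name, value in d.components().items():
            row[f"{name}_dollars"] = economic_gain(round_half_up(value, 2), params)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# golden comparison


@dataclass
class CellComparison:
    table: str
    row: str
    column: str
    expected: str
    computed: float
    passed: bool


@dataclass
class ReproductionReport:
    comparisons: list[CellComparison] = field(default_factory=list)

    @property
    def n_pass(self) -> int:
        return sum(c.passed for c in self.comparisons)

    @property
    def failures(self) -> list[CellComparison]:
        return [c for c in self.comparisons if not c.passed]

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.comparisons])


def _compare_cell(expected: str, computed: float, tol: float = 0.0100001) -> bool:
    """Compare one printed cell with a computed value.

    ``<X`` entries (printed for values below the table's resolution)
    pass when the computed magnitude is below the stated bound.
    """
    expected = str(expected).strip()
    if expected.startswith("<"):
        return abs(computed) < float(expected[1:])
    return abs(float(expected) - computed) <= tol


def _compare_frames(
    name: str, golden: pd.DataFrame, computed: pd.DataFrame, report: ReproductionReport
) -> None:
    key = golden.columns[0]
    comp = computed.copy()
    comp[key] = comp[key].astype(str)
    comp = comp.set_index(key)
    labels = golden[key].astype(str).tolist()
    for col in golden.columns[1:]:
        expected_col = golden[col].astype(str).tolist()
        for label, expected in zip(labels, expected_col):
            value = float(comp.loc[label, col])
            report.comparisons.append(
                CellComparison(
                    table=name,
                    row=label,
                    column=col,
                    expected=expected,
                    computed=value,
                    passed=_compare_cell(expected, value),
                )
            )


def reproduce_study(outdir: str | Path) -> ReproductionReport:
    """Regenerate all published tables from packaged inputs and compare.

    Writes each reproduced table plus a cell-by-cell comparison CSV to
    ``outdir``; the returned report's ``ok`` is False on any mismatch
    beyond +/-0.01.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = ReproductionReport()

    produced = {
        "table5_projection_optimistic": projection_table(OPTIMISTIC),
        "table6_projection_pessimistic": projection_table(PESSIMISTIC),
        "table7_effects_optimistic": effects_table(OPTIMISTIC),
        "table8_effects_pessimistic": effects_table(PESSIMISTIC),
        "table9_scenarios_optimistic": scenario_table(OPTIMISTIC),
        "table10_scenarios_pessimistic": scenario_table(PESSIMISTIC),
    }
    for name, frame in produced.items():
        frame.to_csv(outdir / f"{name}.csv", index=False)
        _compare_frames(name, load_golden(name), frame, report)

    gap_summary().to_csv(outdir / "gap_summary.csv", index=False)
    economic_summary().to_csv(outdir / "economic_summary.csv", index=False)
    pd.DataFrame([per_decade_summary()]).to_csv(
        outdir / "per_decade_rates.csv", index=False
    )
    report.to_frame().to_csv(outdir / "golden_comparison.csv", index=False)
    logger.info(
        "reproduction: %d/%d golden cells pass",
        report.n_pass,
        len(report.comparisons),
    )
    return report


def write_report(
    results: Mapping[str, pd.DataFrame],
    outdir: str | Path,
    format: str = "csv",
) -> list[Path]:
    """Write projection/effect results as CSVs or overview plots.

    ``results`` maps a name to a tidy frame: projection frames need
    ``scenario, period, year, group, value`` columns; effects frames need
    ``period, year`` plus the five component columns.  Empty input writes
    nothing and logs a warning.
    """
    outdir = Path(outdir)
    written: list[Path] = []
    if not results:
        logger.warning("write_report called with empty results; nothing written")
        return written
    outdir.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        for name, frame in results.items():
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
        return written
    if format != "plots":
        raise ValueError(f"unknown report format {format!r}")

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, frame in results.items():
        fig, ax = plt.subplots(figsize=(7, 4.5))
        if "group" in frame.columns:  # projection curves, population only
            pop = frame[frame["group"] == POPULATION]
            for (scenario, period), sub in pop.groupby(["scenario", "period"]):
                ax.plot(sub["year"], sub["value"], label=f"{period} {scenario}")
            ax.set_ylabel("standardized score")
        else:  # effect-size curves
            for col in ("e_base", "e_minor", "e_pop", "e_pm", "e_total"):
                if col in frame.columns:
                    ax.plot(frame["year"], frame[col], label=col)
            ax.set_ylabel("effect (standardized points)")
        ax.set_xlabel("year")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = outdir / f"{name}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        written.append(path)
    return written
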