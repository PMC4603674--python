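"""Synthetic assessment datasets with known ground truth.

The generator emulates the statistical structure of the motivating data:
per-group linear trait trends on a benchmark-standardized scale, two
subjects surveyed in offset calendar years, additive Gaussian survey
noise, and smoothly drifting group composition shares whose per-year sum
never exceeds one.  True standardized levels are inverted through the
standardization formula onto a raw assessment scale, so the whole
pipeline (standardize -> pair -> fit -> anchor -> project -> decompose)
can be exercised end to end against known parameters.

Noise is applied on the standardized scale and mapped back to raw units,
keeping ``noise_sd`` interpretable in standardized points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidScenarioError
from .projection import POPULATION, ShareTable, project
from .standardization import (
    AssessmentObservation,
    build_series,
    pair_survey_years,
    standardize_observations,
)
from .trends import (
    PeriodSpec,
    average_subject_slopes,
    build_trend_model,
    fit_group_slopes,
)
from .decomposition import decompose

__all__ = [
    "SyntheticScenario",
    "RecoveryReport",
    "generate_assessment",
    "generate_shares",
    "recovery_experiment",
    "default_scenario",
]

# Default calibration mirrors the motivating study: four demographic
# groups, mathematics/reading surveyed two years apart over eleven waves
# 1978-2012, subject slopes and 2012 anchor levels at the published
# magnitudes, and census-like share drift 2012 -> 2060.
_GROUPS = ("White", "Black", "Hispanic", "Asian")
_MATH_YEARS = (1978, 1982, 1986, 1990, 1992, 1994, 1996, 1999, 2004, 2008, 2012)
_READ_YEARS = (1980, 1984, 1988, 1990, 1992, 1994, 1996, 1999, 2004, 2008, 2012)
_DEFAULT_SLOPES = {
    ("White", "mathematics"): 0.0914,
    ("White", "reading"): 0.0016,
    ("Black", "mathematics"): 0.1636,
    ("Black", "reading"): 0.1243,
    ("Hispanic", "mathematics"): 0.1990,
    ("Hispanic", "reading"): 0.1089,
    ("Asian", "mathematics"): 0.1186,
    ("Asian", "reading"): 0.2150,
}
_DEFAULT_ANCHORS = {
    "White": 102.28,
    "Black": 91.14,
    "Hispanic": 93.60,
    "Asian": 105.05,
}
_DEFAULT_SHARE_PATH = {
    "White": (0.6298, 0.4258),
    "Black": (0.1234, 0.1316),
    "Hispanic": (0.1689, 0.3064),
    "Asian": (0.0498, 0.0788),
}
# Raw-scale benchmark parameters (0-500 achievement scale): plausible
# subject means/SDs for the reference group-year.
_DEFAULT_RAW_BENCHMARK = {
    "mathematics": (300.4, 34.9),
    "reading": (293.1, 41.3),
}


@dataclass(frozen=True)
class SyntheticScenario:
    """Ground-truth parameters for one synthetic study.

    ``true_slopes`` are standardized points per calendar year per
    (group, subject); ``anchor_levels`` are standardized levels at
    ``anchor_year``; ``share_path`` gives (start, end) proportions
    linearly interpolated between ``share_years``.
    """

    groups: tuple[str, ...] = _GROUPS
    survey_years: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: {
            "mathematics": _MATH_YEARS,
            "reading": _READ_YEARS,
        }
    )
    true_slopes: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_SLOPES)
    )
    anchor_levels: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ANCHORS)
    )
    anchor_year: int = 2012
    raw_benchmark: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RAW_BENCHMARK)
    )
    target_mean: float = 100.0
    target_sd: float = 15.0
    noise_sd: float = 0.5
    share_path: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_SHARE_PATH)
    )
    share_years: tuple[int, int] = (2012, 2060)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidScenarioError("noise_sd must be non-negative")
        if not self.survey_years or any(
            len(ys) == 0 for ys in self.survey_years.values()
        ):
            raise InvalidScenarioError("every subject needs survey years")
        for endpoint in (0, 1):
            total = sum(p[endpoint] for p in self.share_path.values())
            if total > 1 + 1e-9:
                raise InvalidScenarioError(
                    f"share path endpoint sums to {total:.4f} > 1"
                )
        for sd in (sd for _, sd in self.raw_benchmark.values()):
            if sd <= 0:
                raise InvalidScenarioError("raw benchmark sd must be positive")

    @property
    def subjects(self) -> list[str]:
        return list(self.survey_years)

    def true_level(self, group: str, subject: str, year: float) -> float:
        """Noise-free standardized level of a group's subject line."""
        return self.anchor_levels[group] + self.true_slopes[
            (group, subject)
        ] * (year - self.anchor_year)

    def true_average_slope(self, group: str) -> float:
        return average_subject_slopes(
            {s: self.true_slopes[(group, s)] for s in self.subjects}
        )


def _to_raw(scenario: SyntheticScenario, subject: str, std_value: float) -> float:
    """Invert the standardization formula back onto the raw scale."""
    mean, sd = scenario.raw_benchmark[subject]
    return (std_value - scenario.target_mean) / scenario.target_sd * sd + mean


def generate_assessment(
    scenario: SyntheticScenario, rng: np.random.Generator | None = None
) -> list[AssessmentObservation]:
    """Draw one synthetic raw-scale dataset.

    Each observation's raw mean is the noise-free standardized line plus
    N(0, noise_sd) standardized points, mapped to the raw scale; the raw
    SD is the benchmark SD.  Deterministic for a fixed scenario seed.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    obs: list[AssessmentObservation] = []
    for subject in scenario.subjects:
        sd = scenario.raw_benchmark[subject][1]
        for group in scenario.groups:
            for year in scenario.survey_years[subject]:
                std = scenario.true_level(group, subject, year)
                std += rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd else 0.0
                obs.append(
                    AssessmentObservation(
                        group=group,
                        subject=subject,
                        year=int(year),
                        mean=_to_raw(scenario, subject, std),
                        sd=sd,
                    )
                )
    return obs


def generate_shares(
    scenario: SyntheticScenario, years: Sequence[int]
) -> ShareTable:
    """Linearly interpolated composition shares over ``years``."""
    y0, y1 = scenario.share_years
    rows = []
    for year in years:
        if not y0 <= year <= y1:
            raise InvalidScenarioError(
                f"year {year} outside share path range [{y0}, {y1}]"
            )
        w = (year - y0) / (y1 - y0) if y1 > y0 else 0.0
        for group, (p_start, p_end) in scenario.share_path.items():
            rows.append(
                {
                    "year": int(year),
                    "group": group,
                    "proportion": p_start + w * (p_end - p_start),
                }
            )
    return ShareTable(pd.DataFrame(rows))


def fit_scenario(
    scenario: SyntheticScenario,
    observations: Sequence[AssessmentObservation],
    period: PeriodSpec | None = None,
):
    """Run standardize -> pair -> fit -> anchor on one synthetic dataset.

    Standardization uses the scenario's known raw benchmark parameters
    (the generator's ground truth), so recovered levels are directly
    comparable to the scenario's true lines.

    Returns ``(models, slopes)`` where ``slopes[group][subject]`` holds
    per-subject fits plus an ``"average"`` entry.
    """
    from .standardization import Benchmark

    if period is None:
        all_years = [y for ys in scenario.survey_years.values() for y in ys]
        period = PeriodSpec("full", min(all_years), max(all_years))
    benchmark = Benchmark(
        group=scenario.groups[0],
        subject_years={s: min(ys) for s, ys in scenario.survey_years.items()},
        target_mean=scenario.target_mean,
        target_sd=scenario.target_sd,
    )
    std = standardize_observations(
        observations,
        benchmark,
        benchmark_params={s: p for s, p in scenario.raw_benchmark.items()},
    )
    cohorts = pair_survey_years(
        {s: sorted(ys) for s, ys in scenario.survey_years.items()}
    )
    series = build_series(std, cohorts)
    slopes = fit_group_slopes(std, period)
    models = {
        g: build_trend_model(
            series[g], slopes[g]["average"], scenario.anchor_year, period.label
        )
        for g in scenario.groups
    }
    return models, slopes


@dataclass
class RecoveryReport:
    """Parameter-recovery summary over replicate synthetic datasets."""

    replicates: int
    slope_bias: dict[tuple[str, str], float]
    slope_rmse: dict[tuple[str, str], float]
    avg_slope_bias: dict[str, float]
    avg_slope_rmse: dict[str, float]
    max_additivity_violation: float
    projected_population: dict[int, float]

    def worst_rmse(self) -> float:
        return max(self.slope_rmse.values())


def recovery_experiment(
    scenario: SyntheticScenario,
    replicates: int,
    horizon_years: Sequence[int] = (2020, 2040, 2060),
    baseline_group: str | None = None,
) -> RecoveryReport:
    """Estimator bias/RMSE and decomposition-additivity audit.

    Runs the full pipeline on ``replicates`` independent datasets drawn
    from ``scenario`` (replicate streams spawned from the scenario seed),
    then once more noise-free to report the projected population
    trajectory implied by the true parameters.
    """
    if replicates < 1:
        raise InvalidScenarioError("replicates must be >= 1")
    baseline_group = baseline_group or scenario.groups[0]
    years = sorted(set(scenario.share_years) | set(horizon_years))
    shares = generate_shares(scenario, years)

    streams = np.random.SeedSequence(scenario.seed).spawn(replicates)
    errors: dict[tuple[str, str], list[float]] = {
        key: [] for key in scenario.true_slopes
    }
    avg_errors: dict[str, list[float]] = {g: [] for g in scenario.groups}
    max_violation = 0.0
    for stream in streams:
        rng = np.random.default_rng(stream)
        obs = generate_assessment(scenario, rng)
        models, slopes = fit_scenario(scenario, obs)
        for (group, subject), true_m in scenario.true_slopes.items():
            errors[(group, subject)].append(slopes[group][subject] - true_m)
        for group in scenario.groups:
            avg_errors[group].append(
                slopes[group]["average"] - scenario.true_average_slope(group)
            )
        result = project(models, shares, years)
        for year in horizon_years:
            d = decompose(models, shares, year, baseline_group)
            direct = result.at(year, POPULATION) - result.at(
                scenario.anchor_year, POPULATION
            )
            max_violation = max(max_violation, abs(d.e_total - direct))

    # Noise-free reference run: the trajectory implied by the true parameters.
    true_models, _ = fit_scenario(
        scenario, generate_assessment(scenario_noiseless(scenario))
    )
    truth = project(true_models, shares, years)

    def _stats(errs: list[float]) -> tuple[float, float]:
        arr = np.asarray(errs)
        return float(arr.mean()), float(np.sqrt((arr**2).mean()))

    slope_bias, slope_rmse = {}, {}
    for key, errs in errors.items():
        slope_bias[key], slope_rmse[key] = _stats(errs)
    avg_bias, avg_rmse = {}, {}
    for group, errs in avg_errors.items():
        avg_bias[group], avg_rmse[group] = _stats(errs)
    return RecoveryReport(
        replicates=replicates,
        slope_bias=slope_bias,
        slope_rmse=slope_rmse,
        avg_slope_bias=avg_bias,
        avg_slope_rmse=avg_rmse,
        max_additivity_violation=max_violation,
        projected_population={
            y: truth.at(y, POPULATION) for y in truth.values
        },
    )


def scenario_noiseless(scenario: SyntheticScenario) -> SyntheticScenario:
    """Copy of ``scenario`` with the survey noise switched off."""
    from dataclasses import replace

    return replace(scenario, noise_sd=0.0)


def default_scenario(seed: int = 0, noise_sd: float = 0.5) -> SyntheticScenario:
    """The study-calibrated default scenario."""
    return SyntheticScenario(seed=seed, noise_sd=noise_sd)


def analytic_slope_se(years: Sequence[int], noise_sd: float) -> float:
    """Closed-form OLS slope sampling SD: sigma / sqrt(sum (x - xbar)^2)."""
    x = np.asarray(years, dtype=float)
    ssx = float(np.sum((x - x.mean()) ** 2))
    return noise_sd / np.sqrt(ssx)
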