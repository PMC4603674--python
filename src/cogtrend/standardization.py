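"""Benchmark standardization of group-level assessment summaries.

Raw assessment scale scores (e.g. a 0-500 achievement scale) carry no
intrinsic metric.  This module rescales group x subject x year mean scores
onto an IQ-like metric by anchoring a chosen *benchmark* group-year at a
target mean and dispersion (default 100 / 15):

    standardized = (mean - benchmark_mean) / benchmark_sd * target_sd + target_mean

Subjects surveyed in offset calendar years (mathematics in one wave,
reading two years later) are merged into combined cohorts for display,
while each subject keeps its own calendar year for any regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InvalidBenchmarkError, MissingDataError, UnpairedSurveyWarning

__all__ = [
    "AssessmentObservation",
    "Benchmark",
    "Cohort",
    "StandardizedSeries",
    "standardize_score",
    "pair_survey_years",
    "combine_subjects",
    "standardize_observations",
    "build_series",
    "COMBINED_SUBJECT",
]

#: sentinel subject label for rows holding the across-subject mean
COMBINED_SUBJECT = "__combined__"


@dataclass(frozen=True)
class AssessmentObservation:
    """One group x subject x survey-year summary on the raw assessment scale.

    Parameters
    ----------
    group
        Demographic group label.
    subject
        Assessment subject (e.g. ``"mathematics"``).
    year
        Calendar year of the survey.
    mean, sd
        Raw-scale mean and standard deviation of the group.
    share
        Optional proportion of survey participants in this group.
    """

    group: str
    subject: str
    year: int
    mean: float
    sd: float | None = None
    share: float | None = None

    def __post_init__(self) -> None:
        if self.sd is not None and self.sd <= 0:
            raise InvalidBenchmarkError(f"sd must be positive, got {self.sd}")
        if self.share is not None and not 0 <= self.share <= 1:
            raise ValueError(f"share must lie in [0, 1], got {self.share}")


@dataclass(frozen=True)
class Benchmark:
    """Reference group-year(s) anchoring the standardized metric.

    ``subject_years`` maps each subject to the calendar year whose
    benchmark-group mean and SD define the scale for that subject.
    """

    group: str
    subject_years: Mapping[str, int]
    target_mean: float = 100.0
    target_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.target_sd <= 0:
            raise InvalidBenchmarkError(
                f"target_sd must be positive, got {self.target_sd}"
            )


@dataclass(frozen=True)
class Cohort:
    """A display cohort: one or more subject surveys merged under a label."""

    label: str
    subject_years: Mapping[str, int]

    @property
    def cohort_year(self) -> int:
        """Earliest calendar year in the cohort, used for display ordering."""
        return min(self.subject_years.values())


@dataclass
class StandardizedSeries:
    """Ordered standardized trajectory for one group.

    ``points`` are ``(cohort_label, cohort_year, value)`` tuples with
    strictly increasing cohort years.
    """

    group: str
    points: list[tuple[str, int, float]] = field(default_factory=list)

    def value_at(self, year: int) -> float:
        for _, y, v in self.points:
            if y == year:
                return v
        raise KeyError(f"no observation at year {year} for group {self.group!r}")

    def years(self) -> list[int]:
        return [y for _, y, _ in self.points]


def standardize_score(
    mean: float,
    benchmark_mean: float,
    benchmark_sd: float,
    target_mean: float = 100.0,
    target_sd: float = 15.0,
) -> float:
    """Map a raw-scale mean onto the standardized metric.

    The benchmark group-year's mean maps to ``target_mean`` and one raw
    benchmark SD corresponds to ``target_sd`` standardized points.
    """
    if benchmark_sd <= 0:
        raise InvalidBenchmarkError(
            f"benchmark_sd must be positive, got {benchmark_sd}"
        )
    return (mean - benchmark_mean) / benchmark_sd * target_sd + target_mean


def _cohort_label(years: Sequence[int]) -> str:
    uniq = sorted(set(years))
    if len(uniq) == 1:
        return str(uniq[0])
    # "1978/80" style: full first year, two-digit suffix of the later one
    first, last = uniq[0], uniq[-1]
    return f"{first}/{str(last)[-2:]}"


def pair_survey_years(
    subject_years: Mapping[str, Sequence[int]],
    max_gap: int = 2,
) -> list[Cohort]:
    """Merge offset survey waves of different subjects into display cohorts.

    Subjects surveyed within ``max_gap`` years of one another are merged
    under a combined label such as ``"1978/80"``; identical years keep the
    single-year label.  Surveys with no partner inside the gap are emitted
    as singleton cohorts with an :class:`UnpairedSurveyWarning`.

    Greedy earliest-first matching: each subject's sorted year list is
    consumed front to back, pairing the earliest unmatched years across
    subjects whenever they all fall within the gap.
    """
    if not subject_years:
        raise MissingDataError("subject_years is empty")
    queues = {s: list(ys) for s, ys in subject_years.items() if len(ys)}
    cohorts: list[Cohort] = []
    while any(queues.values()):
        heads = {s: q[0] for s, q in queues.items() if q}
        earliest = min(heads.values())
        members = {s: y for s, y in heads.items() if y - earliest <= max_gap}
        if len(members) < len([q for q in queues.values() if q]):
            lonely = [s for s in heads if s not in members]
            if not members:  # pragma: no cover - defensive
                members = {s: heads[s] for s in lonely}
            elif len(members) == 1:
                (only,) = members
                warnings.warn(
                    f"survey {only}:{members[only]} has no partner within "
                    f"{max_gap} years",
                    UnpairedSurveyWarning,
                    stacklevel=2,
                )
        cohorts.append(Cohort(_cohort_label(list(members.values())), dict(members)))
        for s in members:
            queues[s].pop(0)
    return cohorts


def combine_subjects(values: Mapping[str, float]) -> float:
    """Arithmetic mean of per-subject standardized values."""
    if not values:
        raise MissingDataError("no subject values to combine")
    return sum(values.values()) / len(values)


def _benchmark_params(
    observations: Iterable[AssessmentObservation], benchmark: Benchmark
) -> dict[str, tuple[float, float]]:
    """Raw mean/SD of the benchmark group at its benchmark year, per subject."""
    params: dict[str, tuple[float, float]] = {}
    for obs in observations:
        year = benchmark.subject_years.get(obs.subject)
        if obs.group == benchmark.group and obs.year == year:
            if obs.sd is None or obs.sd <= 0:
                raise InvalidBenchmarkError(
                    f"benchmark observation {obs.subject}/{obs.year} lacks a "
                    "positive sd"
                )
            params[obs.subject] = (obs.mean, obs.sd)
    missing = set(benchmark.subject_years) - set(params)
    if missing:
        raise InvalidBenchmarkError(
            f"no benchmark observation for subject(s) {sorted(missing)}"
        )
    return params


def standardize_observations(
    observations: Sequence[AssessmentObservation],
    benchmark: Benchmark,
    exclude_groups: Sequence[str] = (),
    benchmark_params: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Standardize a dataset of raw observations against a benchmark.

    The raw benchmark mean/SD per subject are taken from the benchmark
    group's own observation at its benchmark year, unless known values
    are supplied via ``benchmark_params`` (``subject -> (mean, sd)``),
    e.g. from a synthetic generator's ground truth.

    Groups listed in ``exclude_groups`` (e.g. categories with insufficient
    data) are dropped explicitly.  Returns a tidy frame with columns
    ``group, subject, year, value``.
    """
    if benchmark_params is not None:
        params = dict(benchmark_params)
        for subject, (_, sd) in params.items():
            if sd <= 0:
                raise InvalidBenchmarkError(
                    f"benchmark sd for {subject!r} must be positive"
                )
    else:
        params = _benchmark_params(observations, benchmark)
    rows = []
    for obs in observations:
        if obs.group in exclude_groups:
            continue
        if obs.subject not in params:
            raise InvalidBenchmarkError(
                f"subject {obs.subject!r} has no benchmark year"
            )
        bm, bs = params[obs.subject]
        rows.append(
            {
                "group": obs.group,
                "subject": obs.subject,
                "year": obs.year,
                "value": standardize_score(
                    obs.mean, bm, bs, benchmark.target_mean, benchmark.target_sd
                ),
            }
        )
    return pd.DataFrame(rows, columns=["group", "subject", "year", "value"])


def build_series(
    standardized: pd.DataFrame,
    cohorts: Sequence[Cohort] | None = None,
    max_gap: int = 2,
) -> dict[str, StandardizedSeries]:
    """Assemble per-group combined cohort series from standardized values.

    If ``cohorts`` is not supplied, survey years are paired automatically
    from the frame's subject x year structure.  Each cohort's value is the
    across-subject mean of that cohort's per-subject standardized values.
    """
    if cohorts is None:
        subject_years = {
            s: sorted(g["year"].unique())
            for s, g in standardized.groupby("subject")
        }
        cohorts = pair_survey_years(subject_years, max_gap=max_gap)
    series: dict[str, StandardizedSeries] = {}
    for group, gdf in standardized.groupby("group", sort=False):
        lookup = {(r.subject, r.year): r.value for r in gdf.itertuples()}
        points = []
        for cohort in cohorts:
            vals = {
                s: lookup[(s, y)]
                for s, y in cohort.subject_years.items()
                if (s, y) in lookup
            }
            if vals:
                points.append(
                    (cohort.label, cohort.cohort_year, combine_subjects(vals))
                )
        points.sort(key=lambda p: p[1])
        series[str(group)] = StandardizedSeries(str(group), points)
    return series


def series_to_frame(
    standardized: pd.DataFrame,
    series: Mapping[str, StandardizedSeries],
    cohorts: Sequence[Cohort],
) -> pd.DataFrame:
    """Long output table: per-subject rows plus a combined row per cohort.

    Per-subject rows keep the subject's own calendar year in
    ``cohort_year`` (regressions need it); only the combined rows carry
    the cohort display year.
    """
    label_of = {}
    for cohort in cohorts:
        for s, y in cohort.subject_years.items():
            label_of[(s, y)] = cohort.label
    rows = []
    for r in standardized.itertuples():
        label = label_of.get((r.subject, r.year), str(r.year))
        rows.append(
            {
                "group": r.group,
                "cohort_label": label,
                "cohort_year": r.year,
                "subject": r.subject,
                "value": r.value,
            }
        )
    for group, s in series.items():
        for label, cyear, value in s.points:
            rows.append(
                {
                    "group": group,
                    "cohort_label": label,
                    "cohort_year": cyear,
                    "subject": COMBINED_SUBJECT,
                    "value": value,
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "cohort_label", "cohort_year", "subject", "value"]
    )
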