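"""Stratified (sex x age-bin) e-norms analysis and between-stratum comparisons.

Applies the plateau method separately per stratum, tabulates the cohort's
demographics, and compares male with female plateau values within each age
bin.  The default bins (17-49, 50-69, 70-79, 80-98 years) match the
age groups used in large actuarial BMI/mortality studies so stratified
reference ranges are directly comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortRecord
from .core import (
    DiagnosticsReport,
    EnormsError,
    InvalidInputError,
    NoPlateauError,
    NormativeRange,
    ObservationSeries,
    PlateauBounds,
    PlateauParams,
    run_enorms,
)

logger = logging.getLogger("enorms")

__all__ = [
    "AgeBins",
    "StratumResult",
    "ComparisonResult",
    "StratifiedReport",
    "DEFAULT_AGE_BINS",
    "stratify_cohort",
    "summarize_demographics",
    "compare_strata",
    "quantile_pair",
    "run_stratified_enorms",
]

_SEXES = ("male", "female")
StratumKey = tuple[str, tuple[int, int]]


@dataclass(frozen=True)
class AgeBins:
    """Ordered, non-overlapping inclusive [low, high] age intervals in years.

    Ages below the first bin or above the last (or in a gap between bins)
    are excluded from stratified analysis, mirroring the exclusion of
    under-age subjects at cohort construction.
    """

    edges: tuple[tuple[int, int], ...] = ((17, 49), (50, 69), (70, 79), (80, 98))

    def __post_init__(self) -> None:
        edges = tuple((int(lo), int(hi)) for lo, hi in self.edges)
        if not edges:
            raise InvalidInputError("at least one age bin is required")
        for lo, hi in edges:
            if lo > hi:
                raise InvalidInputError(f"age bin [{lo}, {hi}] has low > high")
        for (_, hi_prev), (lo_next, _) in zip(edges, edges[1:]):
            if lo_next <= hi_prev:
                raise InvalidInputError(
                    f"age bins overlap or are out of order near [{lo_next}, ...]"
                )
        object.__setattr__(self, "edges", edges)

    def assign(self, age: int) -> tuple[int, int] | None:
        """The bin containing ``age`` (inclusive on both edges), or None."""
        for lo, hi in self.edges:
            if lo <= age <= hi:
                return (lo, hi)
        return None

    def labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.edges]


DEFAULT_AGE_BINS = AgeBins()


@dataclass(frozen=True)
class StratumResult:
    """e-norms output for one (sex, age-bin) stratum."""

    key: StratumKey
    n: int
    range: NormativeRange
    bounds: PlateauBounds
    diagnostics: DiagnosticsReport | None
    plateau_values: np.ndarray


@dataclass(frozen=True)
class ComparisonResult:
    """A two-sample comparison between two strata's plateau values."""

    key_a: StratumKey
    key_b: StratumKey
    method: Literal["welch", "paired"]
    statistic: float
    degrees_of_freedom: float
    p_value: float


@dataclass(frozen=True)
class StratifiedReport:
    """Results, skipped strata (with reasons) and male-vs-female comparisons."""

    results: list[StratumResult]
    skipped: list[tuple[StratumKey, str]]
    comparisons: list[ComparisonResult]
    n_excluded: int = 0

    def result_for(self, key: StratumKey) -> StratumResult | None:
        for res in self.results:
            if res.key == key:
                return res
        return None


def _check_sex(rec: CohortRecord) -> str:
    if rec.sex not in _SEXES:
        raise InvalidInputError(
            f"record {rec.subject_id}: unknown sex code {rec.sex!r} "
            f"(expected one of {_SEXES})"
        )
    return rec.sex


def stratify_cohort(
    cohort: Sequence[CohortRecord], bins: AgeBins = DEFAULT_AGE_BINS
) -> dict[StratumKey, ObservationSeries]:
    """Partition a cohort into per-(sex, age-bin) observation series.

    Each record lands in at most one stratum; records whose age falls
    outside every bin are excluded and the count logged.  Empty strata are
    omitted from the result.
    """
    if len(cohort) == 0:
        raise InvalidInputError("cannot stratify an empty cohort")
    buckets: dict[StratumKey, list[float]] = {}
    excluded = 0
    for rec in cohort:
        sex = _check_sex(rec)
        bin_ = bins.assign(rec.age)
        if bin_ is None:
            excluded += 1
            continue
        buckets.setdefault((sex, bin_), []).append(rec.value)
    if excluded:
        logger.info("stratification excluded %d records outside the age bins", excluded)
    return {
        key: ObservationSeries(np.asarray(vals))
        for key, vals in buckets.items()
    }


def count_age_exclusions(cohort: Sequence[CohortRecord], bins: AgeBins) -> int:
    """Number of records whose age falls outside every bin."""
    return sum(1 for rec in cohort if bins.assign(rec.age) is None)


def summarize_demographics(
    cohort: Sequence[CohortRecord], bins: AgeBins = DEFAULT_AGE_BINS
) -> pd.DataFrame:
    """Counts table: rows = age bins plus total, columns = sexes plus total.

    Marginal totals equal the sums of the cells; the grand total equals the
    number of records inside the bins (age-excluded records do not count).
    """
    counts = {label: {sex: 0 for sex in _SEXES} for label in bins.labels()}
    for rec in cohort:
        sex = _check_sex(rec)
        bin_ = bins.assign(rec.age)
        if bin_ is None:
            continue
        counts[f"{bin_[0]}-{bin_[1]}"][sex] += 1
    table = pd.DataFrame(counts).T.loc[bins.labels(), list(_SEXES)]
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    table.index.name = "age_group"
    return table.astype(int)


def quantile_pair(
    a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce two samples to paired values on a common quantile grid.

    Both samples are evaluated at the ``k = min(len(a), len(b))`` mid-point
    probabilities ``(i + 0.5) / k``, producing equal-length, rank-aligned
    vectors suitable for a paired test when the raw strata have unequal
    sizes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    k = min(a.size, b.size)
    if k < 2:
        raise InvalidInputError("quantile pairing requires at least 2 values per side")
    probs = (np.arange(k) + 0.5) / k
    return np.quantile(a, probs), np.quantile(b, probs)


def compare_strata(
    series_a: ObservationSeries | Sequence[float],
    series_b: ObservationSeries | Sequence[float],
    method: Literal["welch", "paired"] = "welch",
    *,
    key_a: StratumKey | None = None,
    key_b: StratumKey | None = None,
) -> ComparisonResult:
    """Two-sided t-test between two samples.

    ``welch`` is the unequal-variance two-sample t-test and is well defined
    for strata of different sizes.  ``paired`` requires equal lengths (use
    :func:`quantile_pair` first to align unequal strata on a common
    quantile grid); identical samples return statistic 0 with p = 1 by
    convention, while a nonzero mean difference with zero difference
    variance is degenerate and raises an error.
    """
    a = np.asarray(
        series_a.values if isinstance(series_a, ObservationSeries) else series_a,
        dtype=float,
    )
    b = np.asarray(
        series_b.values if isinstance(series_b, ObservationSeries) else series_b,
        dtype=float,
    )
    if a.size < 2 or b.size < 2:
        raise InvalidInputError("both samples need at least 2 values")
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        return ComparisonResult(
            key_a=key_a,
            key_b=key_b,
            method="welch",
            statistic=float(res.statistic),
            degrees_of_freedom=float(res.df),
            p_value=float(res.pvalue),
        )
    if method == "paired":
        if a.size != b.size:
            raise InvalidInputError(
                f"paired test requires equal lengths ({a.size} vs {b.size}); "
                "reduce to a common quantile grid first"
            )
        d = a - b
        df = float(d.size - 1)
        if d.std(ddof=1) == 0:
            if d.mean() == 0:
                return ComparisonResult(key_a, key_b, "paired", 0.0, df, 1.0)
            raise InvalidInputError(
                "degenerate paired comparison: constant nonzero differences"
            )
        res = stats.ttest_rel(a, b)
        return ComparisonResult(
            key_a=key_a,
            key_b=key_b,
            method="paired",
            statistic=float(res.statistic),
            degrees_of_freedom=df,
            p_value=float(res.pvalue),
        )
    raise InvalidInputError(f"unknown method {method!r}")


def run_stratified_enorms(
    cohort: Sequence[CohortRecord],
    bins: AgeBins = DEFAULT_AGE_BINS,
    params: PlateauParams | None = None,
    *,
    t_test: Literal["welch", "paired"] = "welch",
    diagnostics: bool = True,
    diagnostics_scope: Literal["plateau", "full"] = "plateau",
    lilliefors_reps: int = 10_000,
    lilliefors_seed: int = 0,
) -> StratifiedReport:
    """Per-stratum e-norms plus male-vs-female comparisons per age bin.

    Strata too small for plateau detection (or without a detectable
    plateau) are reported as skipped with a reason; the run continues.
    Comparisons are made on the plateau values of each stratum: Welch's
    test by default, or a paired test on a common quantile grid (see
    :func:`quantile_pair`) to emulate a paired analysis of unequal strata.
    """
    if params is None:
        params = PlateauParams()
    series_map = stratify_cohort(cohort, bins)
    n_excluded = count_age_exclusions(cohort, bins)
    results: list[StratumResult] = []
    skipped: list[tuple[StratumKey, str]] = []
    ordered_keys = [
        (sex, bin_) for bin_ in (tuple(b) for b in bins.edges) for sex in _SEXES
    ]
    for key in ordered_keys:
        if key not in series_map:
            skipped.append((key, "empty stratum"))
            continue
        series = series_map[key]
        try:
            out = run_enorms(
                series,
                params,
                diagnostics=diagnostics,
                diagnostics_scope=diagnostics_scope,
                lilliefors_reps=lilliefors_reps,
                lilliefors_seed=lilliefors_seed,
            )
        except (InvalidInputError, NoPlateauError) as exc:
            skipped.append((key, str(exc)))
            continue
        plateau = out.plot.sorted_values[out.bounds.a - 1 : out.bounds.b]
        results.append(
            StratumResult(
                key=key,
                n=series.n,
                range=out.range,
                bounds=out.bounds,
                diagnostics=out.diagnostics,
                plateau_values=plateau,
            )
        )
    comparisons: list[ComparisonResult] = []
    by_key = {res.key: res for res in results}
    for bin_ in bins.edges:
        male = by_key.get(("male", bin_))
        female = by_key.get(("female", bin_))
        if male is None or female is None:
            continue
        a, b = male.plateau_values, female.plateau_values
        if t_test == "paired":
            a, b = quantile_pair(a, b)
        try:
            comparisons.append(
                compare_strata(
                    a, b, t_test, key_a=("male", bin_), key_b=("female", bin_)
                )
            )
        except EnormsError as exc:
            logger.warning("comparison for bin %s skipped: %s", bin_, exc)
    return StratifiedReport(
        results=results,
        skipped=skipped,
        comparisons=comparisons,
        n_excluded=n_excluded,
    )
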