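"""The e-norms algorithm.

The method operates on a single continuous variable measured in a mixed
population (healthy subjects plus subjects with pathology):

1. sort the values in ascending order and plot them against rank, giving a
   cumulative "inverted S" curve;
2. compute first-order differences between successive sorted values;
3. locate the plateau -- the longest central stretch where (smoothed)
   differences stay small, bounded by inflection points A and B;
4. report descriptive statistics of the plateau values as the normative
   (reference) range.

Healthy values of a biomarker span a narrow min-to-max interval while
pathological values spread over a much wider one, so the plateau isolates
the healthy sub-population without requiring a screened reference cohort.

The original procedure identifies A and B visually.  Here the plateau is
detected automatically: differences are smoothed with a centered moving
median and the plateau is the longest contiguous run of smoothed
differences not exceeding ``k`` times the median raw difference.  The
defaults (``window=9``, ``k=6``) are calibrated so that on a pure Gaussian
sample the plateau covers approximately the central 95% of the data
(mean +/- 2 SD).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

logger = logging.getLogger("enorms")

__all__ = [
    "EnormsError",
    "InvalidInputError",
    "ParameterError",
    "NoPlateauError",
    "ObservationSeries",
    "RankPlot",
    "PlateauParams",
    "PlateauBounds",
    "NormativeRange",
    "DiagnosticsReport",
    "EnormsResult",
    "sort_and_rank",
    "smooth_differences",
    "detect_plateau",
    "normative_range",
    "run_enorms",
    "distribution_diagnostics",
    "min_max_difference",
    "plot_table",
]


class EnormsError(Exception):
    """Base class for errors raised by this package."""


class InvalidInputError(EnormsError, ValueError):
    """The supplied data violates a precondition (empty, non-finite, ...)."""


class ParameterError(EnormsError, ValueError):
    """An algorithm parameter is out of its valid domain."""


class NoPlateauError(EnormsError):
    """No contiguous low-difference run long enough to qualify as a plateau."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObservationSeries:
    """An unordered series of finite real measurements of one variable.

    Parameters
    ----------
    values
        The raw measurements, in the variable's units (e.g. kg/m^2 for BMI).
        All entries must be finite; non-finite entries are rejected with an
        error naming the offending position.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise InvalidInputError("observation series must be one-dimensional")
        if arr.size < 1:
            raise InvalidInputError("observation series must contain at least one value")
        bad = np.flatnonzero(~np.isfinite(arr))
        if bad.size:
            raise InvalidInputError(
                f"non-finite value at index {int(bad[0])} "
                f"({arr[bad[0]]!r}); {bad.size} non-finite entries in total"
            )
        object.__setattr__(self, "values", arr)

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class RankPlot:
    """Sorted values against 1-based rank, with first-order differences.

    ``diffs[i]`` is the gap between sorted value ``i+1`` and sorted value
    ``i+2`` in 1-based rank terms: it "sits between" ranks ``i+1`` and
    ``i+2``.  ``smoothed_diffs`` is the centered moving median of ``diffs``
    (equal to ``diffs`` when the smoothing window is 1).
    """

    sorted_values: np.ndarray
    ranks: np.ndarray
    diffs: np.ndarray
    smoothed_diffs: np.ndarray
    window: int = 1

    @property
    def n(self) -> int:
        return int(self.sorted_values.size)


@dataclass(frozen=True)
class PlateauParams:
    """Tuning parameters for automatic plateau detection.

    Parameters
    ----------
    window
        Odd span (in rank units) of the centered moving-median smoother
        applied to the first-order differences.  Robust to isolated large
        gaps; 1 disables smoothing.
    k
        Relative threshold multiplier: a difference index belongs to the
        candidate plateau when its smoothed difference is at most
        ``k * median(diffs)``.  Using the median difference makes the rule
        scale-equivariant.
    min_run
        Minimum plateau length in points.  ``None`` (default) resolves to
        ``max(10, ceil(0.05 * n))`` at detection time.
    """

    window: int = 9
    k: float = 6.0
    min_run: int | None = None

    def __post_init__(self) -> None:
        if self.window < 1 or self.window % 2 == 0:
            raise ParameterError(f"window must be an odd positive integer, got {self.window}")
        if not (self.k > 0):
            raise ParameterError(f"k must be positive, got {self.k}")
        if self.min_run is not None and self.min_run < 2:
            raise ParameterError(f"min_run must be >= 2, got {self.min_run}")

    def resolve_min_run(self, n: int) -> int:
        if self.min_run is not None:
            return self.min_run
        return max(10, math.ceil(0.05 * n))


@dataclass(frozen=True)
class PlateauBounds:
    """1-based inclusive indices of inflection points A and B into the
    sorted values.  The plateau is ``sorted_values[a..b]``."""

    a: int
    b: int

    def __post_init__(self) -> None:
        if not (1 <= self.a < self.b):
            raise InvalidInputError(f"require 1 <= a < b, got a={self.a}, b={self.b}")

    @property
    def n_plateau(self) -> int:
        return self.b - self.a + 1


@dataclass(frozen=True)
class NormativeRange:
    """Descriptive statistics of the plateau values.

    The headline reference range is ``[min, max]`` of the plateau values;
    ``mean +/- 2 sd`` is exposed as a secondary interval via
    :attr:`mean_minus_2sd` / :attr:`mean_plus_2sd`.
    """

    n_plateau: int
    mean: float
    sd: float
    min: float
    max: float

    @property
    def mean_minus_2sd(self) -> float:
        return self.mean - 2.0 * self.sd

    @property
    def mean_plus_2sd(self) -> float:
        return self.mean + 2.0 * self.sd


@dataclass(frozen=True)
class DiagnosticsReport:
    """Distribution-shape diagnostics of a sample.

    ``skewness`` and ``excess_kurtosis`` are the population (biased) moment
    estimators; ``excess_kurtosis`` is the fourth standardized moment minus
    3, so a Gaussian scores 0.  ``ks_d`` is the Kolmogorov-Smirnov distance
    to a Gaussian with the sample's own mean and (sample) SD, and
    ``lilliefors_p`` is the Monte-Carlo p-value of that statistic under the
    estimated-parameters null (Lilliefors test), with the seed and replicate
    count recorded for reproducibility.
    """

    skewness: float
    excess_kurtosis: float
    ks_d: float
    lilliefors_p: float
    lilliefors_reps: int = 0
    lilliefors_seed: int = 0


@dataclass(frozen=True)
class EnormsResult:
    """Full output of one e-norms run."""

    plot: RankPlot
    bounds: PlateauBounds
    range: NormativeRange
    diagnostics: DiagnosticsReport | None = None
    params: PlateauParams = field(default_factory=PlateauParams)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _as_series(series: ObservationSeries | Iterable[float]) -> ObservationSeries:
    if isinstance(series, ObservationSeries):
        return series
    return ObservationSeries(np.asarray(list(series), dtype=float))


def sort_and_rank(
    series: ObservationSeries | Iterable[float], window: int = 1
) -> RankPlot:
    """Sort a series ascending and attach ranks and first-order differences.

    The result is the data behind the cumulative rank-order plot: for a
    mixed healthy/pathological sample it traces an inverted S with a flat
    middle.  Input order is irrelevant; sorting is stable so tied values
    keep a deterministic arrangement.

    Parameters
    ----------
    series
        At least two finite measurements.
    window
        Smoothing span recorded on the plot (see :func:`smooth_differences`).

    Raises
    ------
    InvalidInputError
        On an empty or single-point series, or any non-finite value.
    """
    s = _as_series(series)
    if s.n < 2:
        raise InvalidInputError(f"need at least 2 values to rank, got {s.n}")
    sorted_values = np.sort(s.values, kind="stable")
    diffs = np.diff(sorted_values)
    smoothed = smooth_differences(diffs, window)
    return RankPlot(
        sorted_values=sorted_values,
        ranks=np.arange(1, s.n + 1),
        diffs=diffs,
        smoothed_diffs=smoothed,
        window=window,
    )


def smooth_differences(diffs: Sequence[float] | np.ndarray, window: int) -> np.ndarray:
    """Centered moving median of the first-order differences.

    Element ``i`` of the output is the median of ``diffs`` over the window
    of span ``window`` centered at ``i``, truncated at the edges (the first
    and last elements see only the in-range part of their window).  A
    median, unlike a mean, is not dragged upward by a single large gap, so
    isolated outlier gaps inside the plateau do not split it and isolated
    tight pairs in the tails do not masquerade as plateau points.

    ``window=1`` returns the input unchanged.
    """
    d = np.asarray(diffs, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ParameterError(f"window must be an odd positive integer, got {window}")
    if d.size == 0 or window == 1:
        return d.copy()
    if window > d.size:
        raise ParameterError(
            f"window ({window}) exceeds number of differences ({d.size})"
        )
    half = window // 2
    out = np.empty_like(d)
    # interior: full windows, vectorized
    if d.size >= window:
        out[half : d.size - half] = np.median(sliding_window_view(d, window), axis=1)
    # edges: truncated windows
    for i in range(half):
        out[i] = np.median(d[: i + half + 1])
    for i in range(d.size - half, d.size):
        out[i] = np.median(d[i - half :])
    return out


def _qualifying_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs of ``mask`` as (start, stop) 0-based inclusive."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    starts, stops = edges[::2], edges[1::2] - 1
    return list(zip(starts.tolist(), stops.tolist()))


def detect_plateau(plot: RankPlot, params: PlateauParams | None = None) -> PlateauBounds:
    """Locate inflection points A and B automatically.

    A difference index qualifies when its smoothed difference is at most
    ``tau = k * median(diffs)``; the plateau is the longest contiguous run
    of qualifying indices.  Ties between equal-length runs are broken in
    favour of the run whose raw member differences sum smaller (the tighter
    cluster), then the leftmost.  A run over difference indices ``i..j``
    (0-based) maps to 1-based value indices ``a = i + 1``, ``b = j + 2``:
    both endpoints of every qualifying gap belong to the plateau.

    Zero differences (exactly repeated values) always qualify, so heavily
    discretized data is biased toward plateau membership; this is inherent
    to the rule and intentionally not corrected.

    Raises
    ------
    InvalidInputError
        If the series is too small (< max(20, min_run + 2) points).
    NoPlateauError
        If the longest qualifying run is shorter than ``min_run``.
    """
    if params is None:
        params = PlateauParams()
    n = plot.n
    min_run = params.resolve_min_run(n)
    if n < max(20, min_run + 2):
        raise InvalidInputError(
            f"series of {n} points is too small for plateau detection "
            f"(need >= {max(20, min_run + 2)})"
        )
    if n < 100:
        logger.warning(
            "plateau detection on only %d points: estimates are unstable", n
        )
    smoothed = (
        plot.smoothed_diffs
        if plot.window == params.window
        else smooth_differences(plot.diffs, params.window)
    )
    tau = params.k * float(np.median(plot.diffs))
    runs = _qualifying_runs(smoothed <= tau)
    if not runs:
        raise NoPlateauError("no plateau detected: no differences under threshold")
    best: tuple[int, int] | None = None
    best_len = -1
    best_sum = math.inf
    for i, j in runs:
        length = j - i + 1
        run_sum = float(plot.diffs[i : j + 1].sum())
        if length > best_len or (length == best_len and run_sum < best_sum):
            best, best_len, best_sum = (i, j), length, run_sum
    assert best is not None
    # run of L difference indices spans L + 1 values
    if best_len + 1 < min_run:
        raise NoPlateauError(
            f"longest qualifying run covers {best_len + 1} points < min_run {min_run}"
        )
    return PlateauBounds(a=best[0] + 1, b=best[1] + 2)


def normative_range(plot: RankPlot, bounds: PlateauBounds) -> NormativeRange:
    """Descriptive statistics of the values between inflection points A and B.

    ``sd`` uses the sample (n-1 denominator) convention.  The reported
    healthy range is the plateau's min-max; by construction both endpoints
    are members of the input series.
    """
    if bounds.b > plot.n:
        raise InvalidInputError(
            f"bounds [{bounds.a}, {bounds.b}] exceed series length {plot.n}"
        )
    segment = plot.sorted_values[bounds.a - 1 : bounds.b]
    return NormativeRange(
        n_plateau=int(segment.size),
        mean=float(segment.mean()),
        sd=float(segment.std(ddof=1)),
        min=float(segment[0]),
        max=float(segment[-1]),
    )


def _lilliefors_mc(
    d_obs: float, n: int, reps: int, seed: int, chunk: int = 2_000_000
) -> float:
    """Monte-Carlo p-value for the Lilliefors (estimated-parameter KS) test.

    Simulates ``reps`` standard-normal samples of size ``n``, refits mean
    and sample SD to each, and compares their KS distances with ``d_obs``.
    Add-one correction keeps the p-value in (0, 1].  Work is chunked so the
    simulation matrix never exceeds ~``chunk`` floats.
    """
    rng = np.random.default_rng(seed)
    exceed = 0
    done = 0
    rows_per_chunk = max(1, chunk // n)
    grid_hi = np.arange(1, n + 1) / n
    grid_lo = np.arange(0, n) / n
    while done < reps:
        m = min(rows_per_chunk, reps - done)
        sims = rng.standard_normal((m, n))
        sims.sort(axis=1)
        mu = sims.mean(axis=1, keepdims=True)
        sd = sims.std(axis=1, ddof=1, keepdims=True)
        cdf = stats.norm.cdf((sims - mu) / sd)
        d_sim = np.maximum(np.abs(cdf - grid_hi), np.abs(cdf - grid_lo)).max(axis=1)
        exceed += int((d_sim >= d_obs).sum())
        done += m
    return (1 + exceed) / (reps + 1)


def distribution_diagnostics(
    values: Sequence[float] | np.ndarray,
    *,
    lilliefors_reps: int = 10_000,
    lilliefors_seed: int = 0,
) -> DiagnosticsReport:
    """Shape diagnostics: skewness, excess kurtosis, KS distance, Lilliefors p.

    Skewness and kurtosis are the population moment estimators (``[1, 2, 3]``
    scores skewness 0 and excess kurtosis -1.5).  The KS statistic ``d`` is
    computed against a Gaussian with the sample's own mean and sample SD;
    because those parameters are estimated from the data, its p-value comes
    from the Lilliefors Monte-Carlo null rather than the standard KS table.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise InvalidInputError(f"diagnostics require at least 8 values, got {x.size}")
    if not np.isfinite(x).all():
        raise InvalidInputError("diagnostics input contains non-finite values")
    skew = float(stats.skew(x, bias=True))
    exkurt = float(stats.kurtosis(x, fisher=True, bias=True))
    mu, sd = float(x.mean()), float(x.std(ddof=1))
    if sd == 0:
        raise InvalidInputError("diagnostics undefined for a constant sample")
    d_obs = float(stats.kstest(x, "norm", args=(mu, sd)).statistic)
    p = _lilliefors_mc(d_obs, x.size, lilliefors_reps, lilliefors_seed)
    return DiagnosticsReport(
        skewness=skew,
        excess_kurtosis=exkurt,
        ks_d=d_obs,
        lilliefors_p=p,
        lilliefors_reps=lilliefors_reps,
        lilliefors_seed=lilliefors_seed,
    )


def run_enorms(
    series: ObservationSeries | Iterable[float],
    params: PlateauParams | None = None,
    *,
    diagnostics: bool = True,
    diagnostics_scope: Literal["plateau", "full"] = "plateau",
    lilliefors_reps: int = 10_000,
    lilliefors_seed: int = 0,
) -> EnormsResult:
    """The full e-norms pipeline on one series.

    Sorts, differences, detects the plateau, summarizes it into a normative
    range, and (optionally) computes distribution diagnostics on either the
    plateau subset (default -- the diagnostics then describe the derived
    healthy sub-population) or the full series.

    Deterministic given the series and parameters; invariant to input
    permutation; affine-equivariant (running on ``a*x + b`` with ``a > 0``
    yields the same plateau indices and an affinely transformed range).
    """
    if params is None:
        params = PlateauParams()
    s = _as_series(series)
    needed = max(20, params.resolve_min_run(s.n) + 2)
    if s.n < needed:
        raise InvalidInputError(
            f"series of {s.n} points is too small for plateau detection (need >= {needed})"
        )
    plot = sort_and_rank(s, window=params.window)
    bounds = detect_plateau(plot, params)
    rng_ = normative_range(plot, bounds)
    diag = None
    if diagnostics:
        subset = (
            plot.sorted_values[bounds.a - 1 : bounds.b]
            if diagnostics_scope == "plateau"
            else plot.sorted_values
        )
        diag = distribution_diagnostics(
            subset, lilliefors_reps=lilliefors_reps, lilliefors_seed=lilliefors_seed
        )
    return EnormsResult(plot=plot, bounds=bounds, range=rng_, diagnostics=diag, params=params)


def min_max_difference(values: Sequence[float] | np.ndarray) -> float:
    """Spread of a sample: max(values) - min(values).

    The quantity behind "e-norms clustering": healthy fasting glucose spans
    70-99 mg/dl (difference 29) while diabetic values can in theory span
    100-2656 mg/dl (difference 2556) -- normal values cluster, pathological
    values spread.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InvalidInputError("min_max_difference of an empty sample is undefined")
    if not np.isfinite(x).all():
        raise InvalidInputError("input contains non-finite values")
    return float(x.max() - x.min())


def plot_table(plot: RankPlot, bounds: PlateauBounds | None = None) -> pd.DataFrame:
    """Tabulate the rank plot for external plotting.

    Columns: ``rank``, ``value``, ``diff``, ``smoothed_diff`` (the
    difference between this value and the next; NaN on the last row) and
    ``plateau`` (membership flag, all False when ``bounds`` is None).
    Sufficient to redraw the cumulative curve with its first-order
    differences and shaded plateau in any plotting tool.
    """
    n = plot.n
    diff_col = np.append(plot.diffs, np.nan)
    smooth_col = np.append(plot.smoothed_diffs, np.nan)
    member = np.zeros(n, dtype=bool)
    if bounds is not None:
        member[bounds.a - 1 : bounds.b] = True
    return pd.DataFrame(
        {
            "rank": plot.ranks,
            "value": plot.sorted_values,
            "diff": diff_col,
            "smoothed_diff": smooth_col,
            "plateau": member,
        }
    )
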