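"""Unit tests for the core algorithm: sorting, smoothing, plateau
detection, normative-range statistics and distribution diagnostics."""

import numpy as np
import pytest

from enorms.core import (
    InvalidInputError,
    NoPlateauError,
    ObservationSeries,
    ParameterError,
    PlateauBounds,
    PlateauParams,
    distribution_diagnostics,
    min_max_difference,
    normative_range,
    plot_table,
    run_enorms,
    smooth_differences,
    sort_and_rank,
)

from .oracles import brute_moving_median, brute_slice_stats


class TestSortAndRank:
    def test_basic_sorting_and_diffs(self):
        plot = sort_and_rank([3.0, 1.0, 2.0])
        assert plot.sorted_values.tolist() == [1.0, 2.0, 3.0]
        assert plot.ranks.tolist() == [1, 2, 3]
        assert plot.diffs.tolist() == [1.0, 1.0]

    def test_constant_series_has_zero_diffs(self):
        plot = sort_and_rank([5, 5, 5, 5])
        assert plot.diffs.tolist() == [0, 0, 0]

    def test_diff_conservation_on_gaussian(self, gaussian_series):
        plot = sort_and_rank(gaussian_series)
        assert plot.diffs.sum() == pytest.approx(
            gaussian_series.max() - gaussian_series.min(), rel=1e-12
        )
        assert np.all(plot.diffs >= 0)

    def test_sorted_values_preserve_multiset(self, gaussian_series):
        plot = sort_and_rank(gaussian_series)
        assert np.array_equal(np.sort(gaussian_series), plot.sorted_values)

    @pytest.mark.parametrize("bad", [[], [1.0]])
    def test_too_short_series_rejected(self, bad):
        with pytest.raises(InvalidInputError):
            sort_and_rank(bad)

    def test_non_finite_value_named_by_index(self):
        with pytest.raises(InvalidInputError, match="index 2"):
            ObservationSeries(np.array([1.0, 2.0, np.nan, 4.0]))


class TestSmoothDifferences:
    @pytest.mark.parametrize(
        "diffs, window, expected",
        [
            ([0, 0, 9, 0, 0], 3, [0, 0, 0, 0, 0]),  # lone spike removed
            ([1, 2, 3], 3, [1.5, 2, 2.5]),  # edge-truncated medians
            ([4, 1, 7, 2], 1, [4, 1, 7, 2]),  # window 1 is identity
        ],
    )
    def test_hand_computed_medians(self, diffs, window, expected):
        assert smooth_differences(diffs, window).tolist() == expected

    @pytest.mark.parametrize("window", [2, 0, -3])
    def test_invalid_window_rejected(self, window):
        with pytest.raises(ParameterError):
            smooth_differences([1.0, 2.0, 3.0], window)

    def test_window_larger_than_data_rejected(self):
        with pytest.raises(ParameterError):
            smooth_differences([1.0, 2.0], 5)

    @pytest.mark.parametrize("window", [3, 5, 9])
    def test_matches_loop_oracle_on_random_diffs(self, rng, window):
        diffs = rng.exponential(1.0, 40)
        expected = brute_moving_median(diffs.tolist(), window)
        assert smooth_differences(diffs, window) == pytest.approx(expected)


class TestDetectPlateau:
    def test_arithmetic_progression_is_all_plateau(self):
        from enorms import detect_plateau

        plot = sort_and_rank(np.arange(50, dtype=float))
        bounds = detect_plateau(plot, PlateauParams())
        assert (bounds.a, bounds.b) == (1, 50)

    def test_dense_block_flanked_by_wide_tails(self):
        # 50 points 0.01 apart between 10 points spaced 1.0 apart each side
        left = np.arange(10) * 1.0
        dense = 9.0 + 0.01 * np.arange(1, 51)
        right = dense[-1] + 1.0 * np.arange(1, 11)
        values = np.concatenate([left, dense, right])
        params = PlateauParams(window=3, k=6.0, min_run=10)
        from enorms import detect_plateau

        plot = sort_and_rank(values, window=3)
        bounds = detect_plateau(plot, params)
        from .oracles import brute_plateau

        assert (bounds.a, bounds.b) == brute_plateau(values.tolist(), 3, 6.0, 10)
        # the detected plateau is the dense block (up to smoothing blur at the seams)
        assert abs(bounds.a - 11) <= 2 and abs(bounds.b - 60) <= 2

    def test_gaussian_plateau_near_two_sigma(self, gaussian_series):
        from enorms import detect_plateau

        plot = sort_and_rank(gaussian_series, window=9)
        bounds = detect_plateau(plot, PlateauParams())
        rng_ = normative_range(plot, bounds)
        assert 16.0 < rng_.min < 18.0
        assert 22.0 < rng_.max < 24.0

    def test_too_small_series_is_an_error(self):
        from enorms import detect_plateau

        plot = sort_and_rank(np.arange(10, dtype=float))
        with pytest.raises(InvalidInputError):
            detect_plateau(plot, PlateauParams())

    def test_no_plateau_when_min_run_unreachable(self, rng):
        from enorms import detect_plateau

        # widely log-spread values: no long run of small differences
        values = np.exp(rng.uniform(0, 30, 60))
        plot = sort_and_rank(values, window=1)
        with pytest.raises(NoPlateauError):
            detect_plateau(plot, PlateauParams(window=1, k=0.001, min_run=30))


class TestNormativeRange:
    def test_hand_computed_sample_statistics(self):
        plot = sort_and_rank([17.0, 19.0, 21.0, 23.0])
        rng_ = normative_range(plot, PlateauBounds(a=1, b=4))
        assert rng_.n_plateau == 4
        assert rng_.mean == pytest.approx(20.0)
        assert rng_.min == 17.0 and rng_.max == 23.0
        assert rng_.sd == pytest.approx(2.581988897, abs=1e-8)
        assert rng_.mean_minus_2sd == pytest.approx(20.0 - 2 * rng_.sd)

    def test_constant_plateau_degenerates_cleanly(self):
        plot = sort_and_rank([5, 5, 5, 7, 9])
        rng_ = normative_range(plot, PlateauBounds(a=1, b=3))
        assert (rng_.mean, rng_.sd, rng_.min, rng_.max) == (5, 0, 5, 5)

    def test_matches_brute_force_slice_statistics(self, rng):
        values = rng.normal(0, 1, 80)
        plot = sort_and_rank(values)
        for a, b in [(1, 80), (5, 40), (30, 31)]:
            got = normative_range(plot, PlateauBounds(a=a, b=b))
            want = brute_slice_stats(values.tolist(), a, b)
            for field_ in ("n_plateau", "mean", "sd", "min", "max"):
                assert getattr(got, field_) == pytest.approx(want[field_], rel=1e-12)

    def test_out_of_range_bounds_rejected(self):
        plot = sort_and_rank([1.0, 2.0, 3.0])
        with pytest.raises(InvalidInputError):
            normative_range(plot, PlateauBounds(a=2, b=9))


class TestDiagnostics:
    def test_three_point_population_moments(self):
        rep = distribution_diagnostics(
            [1, 2, 3, 1, 2, 3, 1, 2, 3], lilliefors_reps=100
        )
        assert rep.skewness == pytest.approx(0.0, abs=1e-12)
        assert rep.excess_kurtosis == pytest.approx(-1.5, abs=1e-12)

    def test_mirrored_sample_has_zero_skewness(self, rng):
        x = rng.exponential(1, 50)
        sym = np.concatenate([x, -x])  # mirror about 0
        rep = distribution_diagnostics(sym, lilliefors_reps=100)
        assert rep.skewness == pytest.approx(0.0, abs=1e-12)

    def test_large_gaussian_sample_moments_near_zero(self):
        x = np.random.default_rng(99).normal(0, 1, 10_000)
        rep = distribution_diagnostics(x, lilliefors_reps=100)
        assert abs(rep.skewness) < 0.1
        assert abs(rep.excess_kurtosis) < 0.2

    def test_ks_d_matches_statsmodels_lilliefors(self, rng):
        from statsmodels.stats.diagnostic import lilliefors

        x = rng.normal(5, 2, 300)
        d_sm, _ = lilliefors(x, dist="norm", pvalmethod="table")
        rep = distribution_diagnostics(x, lilliefors_reps=100)
        assert rep.ks_d == pytest.approx(d_sm, abs=1e-12)

    def test_monte_carlo_p_tracks_statsmodels_table(self, rng):
        from statsmodels.stats.diagnostic import lilliefors

        gauss = rng.normal(0, 3, 400)
        skewed = np.concatenate([gauss, rng.exponential(3, 200) + 6])
        for x in (gauss, skewed):
            _, p_sm = lilliefors(x, dist="norm", pvalmethod="table")
            rep = distribution_diagnostics(x, lilliefors_reps=2000, lilliefors_seed=0)
            # the table clips at [0.001, 0.2]-ish; agree within a coarse band
            assert rep.lilliefors_p == pytest.approx(p_sm, abs=0.12)

    def test_p_is_deterministic_given_seed(self, rng):
        x = rng.normal(0, 1, 100)
        r1 = distribution_diagnostics(x, lilliefors_reps=500, lilliefors_seed=7)
        r2 = distribution_diagnostics(x, lilliefors_reps=500, lilliefors_seed=7)
        assert r1.lilliefors_p == r2.lilliefors_p

    def test_small_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            distribution_diagnostics([1, 2, 3])


class TestRunEnorms:
    def test_permutation_invariance(self, rng, gaussian_series):
        perm = rng.permutation(gaussian_series)
        r1 = run_enorms(gaussian_series, diagnostics=False)
        r2 = run_enorms(perm, diagnostics=False)
        assert (r1.bounds.a, r1.bounds.b) == (r2.bounds.a, r2.bounds.b)
        assert r1.range == r2.range

    def test_affine_equivariance(self, gaussian_series):
        a, b = 2.0, 10.0
        r1 = run_enorms(gaussian_series, diagnostics=False)
        r2 = run_enorms(a * gaussian_series + b, diagnostics=False)
        assert (r1.bounds.a, r1.bounds.b) == (r2.bounds.a, r2.bounds.b)
        assert r2.range.mean == pytest.approx(a * r1.range.mean + b, rel=1e-12)
        assert r2.range.min == pytest.approx(a * r1.range.min + b, rel=1e-12)
        assert r2.range.max == pytest.approx(a * r1.range.max + b, rel=1e-12)
        assert r2.range.sd == pytest.approx(a * r1.range.sd, rel=1e-12)

    def test_diagnostics_scope_selects_subset(self, gaussian_series):
        on_plateau = run_enorms(gaussian_series, lilliefors_reps=200)
        on_full = run_enorms(
            gaussian_series, diagnostics_scope="full", lilliefors_reps=200
        )
        # plateau truncates the tails, so its excess kurtosis is more negative
        assert on_plateau.diagnostics.excess_kurtosis < on_full.diagnostics.excess_kurtosis


class TestMinMaxDifference:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([70, 99], 29),  # healthy fasting glucose spread (mg/dl)
            ([100, 2656], 2556),  # theoretical diabetic spread (mg/dl)
            ([7.5], 0),
        ],
    )
    def test_clustering_spreads(self, values, expected):
        assert min_max_difference(values) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            min_max_difference([])


class TestPlotTable:
    def test_table_columns_and_plateau_flag(self, gaussian_series):
        result = run_enorms(gaussian_series, diagnostics=False)
        table = plot_table(result.plot, result.bounds)
        assert list(table.columns) == ["rank", "value", "diff", "smoothed_diff", "plateau"]
        assert len(table) == 1000
        assert np.isnan(table["diff"].iloc[-1])
        assert table["plateau"].sum() == result.range.n_plateau
        member_vals = table.loc[table["plateau"], "value"]
        assert member_vals.min() == result.range.min
        assert member_vals.max() == result.range.max
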