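"""Classification, boundary estimation and distribution statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sacfield.srt_analysis import (
    HistogramSpec,
    SRTSample,
    classify_saccades,
    compare_samples,
    empirical_cdf,
    estimate_anticipatory_boundary,
    fraction_exceeding,
    histogram_proportions,
    mse,
    quantile_table,
    r_squared,
    rank_sum_test,
    wasserstein_1d,
)

from oracles import brute_force_wasserstein, exact_rank_sum_p


class TestClassification:
    @pytest.mark.parametrize(
        "srt, species, expected",
        [
            (40, "marmoset", "anticipatory"),
            (-20, "marmoset", "anticipatory"),
            (60, "marmoset", "express"),
            (74, "marmoset", "express"),
            (75, "marmoset", "regular"),
            (80, "marmoset", "regular"),
            (60, "human", "express"),
            (99, "human", "express"),
            (100, "human", "regular"),
            (147, "human", "regular"),
        ],
    )
    def test_species_windows(self, srt, species, expected):
        assert classify_saccades([srt], species)[0] == expected

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(-100, 500), min_size=1, max_size=50))
    def test_partition(self, values):
        for species in ("marmoset", "human"):
            cats = classify_saccades(values, species)
            assert set(cats) <= {"anticipatory", "express", "regular"}
            assert len(cats) == len(values)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            classify_saccades([100], "macaque")


class TestAnticipatoryBoundary:
    def test_recovers_constructed_boundary(self):
        # errant saccades concentrated below 60 ms, correct above
        rng = np.random.default_rng(0)
        low = rng.uniform(20, 60, 400)
        high = rng.uniform(61, 200, 1600)
        sample = SRTSample(
            values=np.concatenate([low, high]),
            correct=np.concatenate([rng.random(400) < 0.35, np.ones(1600, bool)]),
        )
        boundary, flagged = estimate_anticipatory_boundary(sample)
        assert not flagged
        assert abs(boundary - 60.0) <= 6.0

    def test_all_correct_sample_is_flagged(self):
        sample = SRTSample(values=np.array([100.0, 130.0]), correct=np.array([True, True]))
        boundary, flagged = estimate_anticipatory_boundary(sample)
        assert flagged
        assert boundary == 96.0  # minimum-latency bin edge (6 ms bins)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            estimate_anticipatory_boundary(SRTSample(values=np.array([])))

    def test_labels_required(self):
        with pytest.raises(ValueError):
            estimate_anticipatory_boundary(SRTSample(values=np.array([100.0])))


class TestHistogramAndCdf:
    def test_single_value_occupies_one_bin(self):
        p, _ = histogram_proportions([100.0])
        assert p.sum() == pytest.approx(1.0)
        assert (p > 0).sum() == 1 and p.max() == 1.0

    def test_two_values_in_different_bins_split_evenly(self):
        p, _ = histogram_proportions([100.0, 130.0])
        assert sorted(p[p > 0]) == [0.5, 0.5]

    def test_uniform_grid_gives_flat_histogram(self):
        values = np.arange(0.0, 450.0, 1.0)
        p, edges = histogram_proportions(values)
        expected = 6.0 / 450.0
        assert np.allclose(p, expected)

    def test_cdf_properties(self):
        xs, f = empirical_cdf([5.0, 1.0, 3.0, 3.0])
        assert np.all(np.diff(xs) >= 0)
        assert np.all(np.diff(f) >= 0)
        assert f[-1] == 1.0

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.floats(0, 440), min_size=1, max_size=100))
    def test_differencing_binned_cdf_recovers_histogram(self, values):
        p, _ = histogram_proportions(values)
        binned_cdf = np.cumsum(p)
        recovered = np.diff(np.concatenate([[0.0], binned_cdf]))
        assert np.max(np.abs(recovered - p)) < 1e-12


class TestFitStatistics:
    def test_r_squared_identical_is_one(self):
        assert r_squared([0.2, 0.3, 0.5], [0.2, 0.3, 0.5]) == 1.0

    def test_r_squared_mean_model_is_zero(self):
        obs = np.array([0.2, 0.3, 0.5])
        assert r_squared(obs, np.full(3, obs.mean())) == pytest.approx(0.0)

    def test_r_squared_hand_computed_example(self):
        assert r_squared([0.2, 0.3, 0.5], [0.25, 0.25, 0.5]) == pytest.approx(
            0.8929, abs=1e-3
        )

    def test_r_squared_at_most_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            o, m = rng.random(10), rng.random(10)
            assert r_squared(o, m) <= 1.0

    def test_mse_hand_computed_example(self):
        assert mse([0.5, 0.5], [0.4, 0.6]) == pytest.approx(0.01)
        assert mse([0.5, 0.5], [0.5, 0.5]) == 0.0
        assert mse([0.1, 0.9], [0.3, 0.7]) == mse([0.3, 0.7], [0.1, 0.9])


class TestWasserstein:
    def test_identical_samples_zero(self):
        assert wasserstein_1d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_point_masses(self):
        assert wasserstein_1d([0.0], [5.0]) == pytest.approx(5.0)

    def test_translation_property(self):
        rng = np.random.default_rng(2)
        xs = rng.normal(120, 30, 200)
        assert wasserstein_1d(xs, xs + 17.0) == pytest.approx(17.0, abs=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(st.floats(0, 300), min_size=4, max_size=12),
        st.lists(st.floats(0, 300), min_size=4, max_size=12),
    )
    def test_metric_properties_against_optimal_transport(self, xs, ys):
        n = min(len(xs), len(ys))
        xs, ys = np.array(xs[:n]), np.array(ys[:n])
        d_xy = wasserstein_1d(xs, ys)
        assert d_xy == pytest.approx(wasserstein_1d(ys, xs), abs=1e-9)
        assert d_xy == pytest.approx(brute_force_wasserstein(xs, ys), abs=1e-9)
        zs = (np.sort(xs) + np.sort(ys)) / 2.0
        d_xz, d_zy = wasserstein_1d(xs, zs), wasserstein_1d(zs, ys)
        assert d_xy <= d_xz + d_zy + 1e-9


class TestQuantilesAndRankSum:
    def test_median_of_three(self):
        qt = quantile_table([1.0, 2.0, 3.0], [0.5])
        assert qt["quantile_ms"].iloc[0] == 2.0

    def test_linear_interpolation_convention(self):
        qt = quantile_table([0.0, 10.0], [0.25])
        assert qt["quantile_ms"].iloc[0] == 2.5

    def test_exact_small_sample_p(self):
        _, p = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(1 / 3)
        assert p == pytest.approx(exact_rank_sum_p([1.0, 2.0], [3.0, 4.0]))

    def test_exact_matches_enumeration_on_random_samples(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = list(rng.choice(1000, size=5, replace=False).astype(float))
            b = list(rng.choice(2000, size=6, replace=False) + 0.5)
            _, p = rank_sum_test(a, b)
            assert p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-9)

    def test_identical_samples_give_p_one(self):
        xs = list(np.arange(30.0))
        _, p = rank_sum_test(xs, xs)
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestFractionExceeding:
    def test_examples(self):
        assert fraction_exceeding([100.0, 300.0], 250.0) == 0.5
        assert fraction_exceeding([100.0, 200.0], 250.0) == 0.0
        with pytest.raises(ValueError):
            fraction_exceeding([], 250.0)


class TestComparisonReport:
    def test_self_comparison_is_perfect(self):
        rng = np.random.default_rng(8)
        xs = rng.uniform(60, 300, 500)
        report = compare_samples(xs, xs)
        assert report.r_squared == 1.0
        assert report.mse == 0.0
        assert report.wasserstein_ms == 0.0
        assert np.allclose(report.observed_cdf, report.model_cdf)

    def test_histograms_normalised_on_common_bins(self):
        rng = np.random.default_rng(9)
        report = compare_samples(rng.uniform(60, 200, 300), rng.uniform(90, 400, 400))
        assert report.observed_proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert report.model_proportions.sum() == pytest.approx(1.0, abs=1e-9)
        assert report.edges.size == report.observed_proportions.size + 1
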