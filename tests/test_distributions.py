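import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adipowaves.distributions import (
    SizeDistribution,
    export_heatmap_matrix,
    fractional_difference,
    make_log_grid,
    mean_distribution,
    normalize_to_percent,
    read_dataset,
    write_dataset,
)
from conftest import build_dataset


class TestLogGrid:
    def test_default_grid_is_80_log_bins_from_20_to_240(self):
        g = make_log_grid(80, 20, 240)
        assert len(g.edges) == 81
        assert g.edges[0] == pytest.approx(20.0)
        assert g.edges[-1] == pytest.approx(240.0)
        ratios = g.edges[1:] / g.edges[:-1]
        assert np.allclose(ratios, (240 / 20) ** (1 / 80), rtol=1e-9)

    @pytest.mark.parametrize(
        "n,lo,hi,expected",
        [
            (1, 20, 240, [20, 240]),
            (4, 10, 160, [10, 20, 40, 80, 160]),
        ],
    )
    def test_small_grids(self, n, lo, hi, expected):
        assert np.allclose(make_log_grid(n, lo, hi).edges, expected)

    @pytest.mark.parametrize("n,lo,hi", [(0, 20, 240), (10, -1, 240), (10, 240, 20)])
    def test_invalid_arguments_rejected(self, n, lo, hi):
        with pytest.raises(ValueError):
            make_log_grid(n, lo, hi)

    def test_centers_are_geometric_means(self):
        g = make_log_grid(4, 10, 160)
        assert np.allclose(g.centers, np.sqrt(g.edges[:-1] * g.edges[1:]))


class TestNormalizeToPercent:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([1, 1, 2], [25, 25, 50]),
            ([6000, 0, 0], [100, 0, 0]),
        ],
    )
    def test_proportional_to_counts(self, counts, expected):
        assert np.allclose(normalize_to_percent(counts), expected)

    def test_all_zero_is_degenerate(self):
        with pytest.raises(ValueError):
            normalize_to_percent([0.0, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=30).filter(lambda v: sum(v) > 0))
    def test_output_sums_to_100(self, counts):
        assert normalize_to_percent(counts).sum() == pytest.approx(100.0, abs=1e-6)


class TestMeanDistribution:
    def test_identical_days_are_a_fixed_point(self):
        ds = build_dataset({0: [[40, 60]], 7: [[40, 60]], 20: [[40, 60]]}, n_bins=2)
        assert np.allclose(mean_distribution(ds), [40, 60])

    def test_two_day_symmetry(self):
        ds = build_dataset({0: [[100, 0]], 5: [[0, 100]]}, n_bins=2)
        assert np.allclose(mean_distribution(ds), [50, 50])

    def test_matches_bruteforce_day_weighted_average(self, three_day_dataset):
        # replicates averaged within day first, then equal weight per day
        expect = np.mean(
            [
                np.mean([[30, 70], [34, 66]], axis=0),
                np.mean([[50, 50], [46, 54]], axis=0),
                np.mean([[20, 80], [24, 76]], axis=0),
            ],
            axis=0,
        )
        assert np.allclose(mean_distribution(three_day_dataset), expect)
        assert mean_distribution(three_day_dataset).sum() == pytest.approx(100.0)

    def test_unequal_replicate_counts_do_not_bias_day_weights(self):
        ds = build_dataset(
            {0: [[100, 0]] * 3, 5: [[0, 100]]},
            n_bins=2,
        )
        assert np.allclose(mean_distribution(ds), [50, 50])


class TestFractionalDifference:
    def test_identical_vectors_give_zero(self):
        m = np.array([40.0, 60.0])
        assert np.all(fractional_difference(m, m) == 0.0)

    def test_arithmetic_example(self):
        out = fractional_difference([30.0, 70.0], [20.0, 80.0])
        assert np.allclose(out, [0.5, -0.125])

    def test_matches_elementwise_recomputation(self, three_day_dataset):
        mean = mean_distribution(three_day_dataset)
        day = three_day_dataset.day_mean(5)
        out = fractional_difference(day, mean)
        for i in range(2):
            assert out[i] == pytest.approx((day[i] - mean[i]) / mean[i])

    def test_zero_mean_bins_marked_nan(self):
        out = fractional_difference([1.0, 2.0], [0.0, 4.0])
        assert np.isnan(out[0]) and out[1] == pytest.approx(-0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fractional_difference([1.0], [1.0, 2.0])


class TestDatasetIO:
    def test_round_trip_preserves_values(self, tmp_path, three_day_dataset):
        path = tmp_path / "ds.csv"
        write_dataset(three_day_dataset, path)
        back = read_dataset(path)
        assert back.animal_id == three_day_dataset.animal_id
        assert back.days == three_day_dataset.days
        assert back.grid.n_bins == 2
        np.testing.assert_allclose(
            back.values_matrix(), three_day_dataset.values_matrix(), atol=1e-9
        )

    def test_bin_count_mismatch_reported(self, tmp_path, three_day_dataset):
        path = tmp_path / "ds.csv"
        write_dataset(three_day_dataset, path)
        text = path.read_text().replace("n=2", "n=3")
        path.write_text(text)
        with pytest.raises(ValueError, match="value columns"):
            read_dataset(path)

    def test_unsorted_days_sorted_on_load(self, tmp_path):
        path = tmp_path / "ds.csv"
        path.write_text(
            "# grid: n=2 dmin=20 dmax=240\n"
            "animal_id,day,replicate,bin_001,bin_002\n"
            "a,9,r1,50,50\n"
            "a,0,r1,40,60\n"
            "a,3,r1,30,70\n"
        )
        ds = read_dataset(path)
        assert ds.days == [0, 3, 9]
        # row multiset preserved
        rows = sorted((m.day, tuple(m.values)) for m in ds.measurements)
        assert rows == [(0, (40.0, 60.0)), (3, (30.0, 70.0)), (9, (50.0, 50.0))]

    def test_missing_grid_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("animal_id,day,replicate,bin_001\n")
        with pytest.raises(ValueError, match="grid"):
            read_dataset(path)


class TestHeatmapMatrix:
    def test_row_per_day_replicates_averaged(self, three_day_dataset):
        mat = export_heatmap_matrix(three_day_dataset)
        assert list(mat.index) == [0, 5, 10]
        assert mat.shape == (3, 2)
        np.testing.assert_allclose(mat.loc[5], np.mean([[50, 50], [46, 54]], axis=0))

    def test_single_day_dataset(self):
        ds = build_dataset({0: [[100.0, 0.0]]}, n_bins=2)
        assert export_heatmap_matrix(ds).shape == (1, 2)


class TestInvariants:
    def test_stored_distributions_must_sum_to_100(self):
        with pytest.raises(ValueError, match="sum to 100"):
            SizeDistribution(day=0, replicate_id="r1", values=np.array([50.0, 49.0]))

    def test_negative_percentages_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SizeDistribution(day=0, replicate_id="r1", values=np.array([-1.0, 101.0]))
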