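import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_histogram
from cytozone.preprocess import (
    DegenerateHistogramError,
    Histogram,
    binarize,
    compute_histogram,
    despeckle,
    fill_holes,
    largest_component,
    median_filter_2d,
    moments_threshold,
    otsu_threshold,
    percentile_threshold,
)
from oracles import (
    despeckle_oracle,
    fill_holes_oracle,
    largest_component_oracle,
    median3_oracle,
    moments_oracle,
    otsu_oracle,
    percentile_oracle,
)


def _hist(counts):
    counts = np.asarray(counts, dtype=np.int64)
    edges = np.arange(len(counts) + 1, dtype=float)
    return Histogram(counts=counts, bin_edges=edges)


class TestHistogram:
    def test_constant_raster_fills_single_bin(self):
        ch = np.full((10, 10), 7, dtype=np.uint8)
        h = compute_histogram(ch)
        assert h.counts[7] == 100 and h.total == 100

    def test_two_value_8bit_raster(self):
        ch = np.array([0] * 60 + [255] * 40, dtype=np.uint8).reshape(10, 10)
        h = compute_histogram(ch)
        assert h.counts[0] == 60 and h.counts[255] == 40

    def test_16bit_binning_is_floor_div_256(self):
        rng = np.random.default_rng(0)
        ch = rng.integers(0, 2**16, size=(32, 32)).astype(np.uint16)
        h = compute_histogram(ch, n_bins=256)
        direct = np.bincount(ch.ravel() // 256, minlength=256)
        np.testing.assert_array_equal(h.counts, direct)

    def test_empty_raster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_histogram(np.zeros((0,), dtype=np.uint8))


class TestThresholds:
    def test_otsu_two_spike_tie_breaks_low(self):
        counts = np.zeros(256, dtype=int)
        counts[10] = 100
        counts[200] = 100
        assert otsu_threshold(_hist(counts)) == 10

    def test_degenerate_histogram_rejected_by_all_methods(self):
        counts = np.zeros(256, dtype=int)
        counts[42] = 500
        for f in (otsu_threshold, moments_threshold, percentile_threshold):
            with pytest.raises(DegenerateHistogramError):
                f(_hist(counts))

    def test_moments_symmetric_two_spike_separates(self):
        counts = np.zeros(64, dtype=int)
        counts[8] = 50
        counts[40] = 50
        t = moments_threshold(_hist(counts))
        assert 8 <= t < 40

    @pytest.mark.parametrize("counts,fraction,expected", [
        (np.ones(256, dtype=int), 0.5, 127),
        ({0: 30, 128: 30, 255: 40}, 0.5, 128),
    ])
    def test_percentile_examples(self, counts, fraction, expected):
        if isinstance(counts, dict):
            arr = np.zeros(256, dtype=int)
            for k, v in counts.items():
                arr[k] = v
            counts = arr
        assert percentile_threshold(_hist(counts), fraction) == expected

    def test_percentile_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            percentile_threshold(_hist(np.ones(16, dtype=int)), 1.5)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_thresholds_match_independent_oracles(self, seed):
        rng = np.random.default_rng(seed)
        counts = random_histogram(rng, n_bins=64)
        h = _hist(counts)
        assert otsu_threshold(h) == otsu_oracle(counts)
        assert moments_threshold(h) == moments_oracle(counts)
        frac = float(rng.uniform(0.05, 0.95))
        assert percentile_threshold(h, frac) == percentile_oracle(counts, frac)


class TestBinarize:
    def test_two_level_image_exact_mask(self):
        ch = np.where(np.arange(100).reshape(10, 10) < 50, 10, 200).astype(np.uint8)
        mask = binarize(ch, "otsu")
        np.testing.assert_array_equal(mask, ch == 200)

    def test_all_foreground_impossible(self):
        rng = np.random.default_rng(4)
        ch = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
        for method in ("otsu", "moments", "percentile"):
            assert not binarize(ch, method).all()

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown threshold method"):
            binarize(np.zeros((4, 4), dtype=np.uint8), "triangle")


class TestMorphology:
    def test_single_isolated_pixel_removed(self):
        m = np.zeros((9, 9), dtype=bool)
        m[4, 4] = True
        assert not despeckle(m).any()

    def test_annulus_fills_to_disk(self):
        m = np.zeros((11, 11), dtype=bool)
        m[2:9, 2:9] = True
        m[4:7, 4:7] = False
        filled = fill_holes(m)
        assert filled[5, 5] and filled.sum() == 49

    def test_hole_open_to_border_unfilled(self):
        m = np.ones((8, 8), dtype=bool)
        m[0:5, 4] = False  # channel from the border into the interior
        np.testing.assert_array_equal(fill_holes(m), m)

    def test_largest_component_keeps_bigger_blob(self):
        m = np.zeros((12, 12), dtype=bool)
        m[1:3, 1:4] = True        # 6 px (largest is 9 below)
        m[6:9, 6:9] = True        # 9 px
        kept = largest_component(m)
        assert kept.sum() == 9 and kept[7, 7] and not kept[1, 1]

    def test_largest_component_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = largest_component(np.zeros((4, 4), dtype=bool))
        assert not out.any()

    def test_equal_size_tie_goes_to_earlier_raster_component(self):
        m = np.zeros((10, 10), dtype=bool)
        m[1, 1:4] = True   # first pixel (1,1)
        m[5, 5:8] = True   # first pixel (5,5)
        kept = largest_component(m)
        assert kept[1, 1] and not kept[5, 5]

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_morphology_matches_bruteforce_oracles(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((16, 16)) < rng.uniform(0.15, 0.7)
        np.testing.assert_array_equal(despeckle(m), despeckle_oracle(m))
        np.testing.assert_array_equal(fill_holes(m), fill_holes_oracle(m))
        if m.any():
            np.testing.assert_array_equal(largest_component(m), largest_component_oracle(m))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_morphology_invariants(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.random((16, 16)) < rng.uniform(0.15, 0.7)
        d, f = despeckle(m), fill_holes(m)
        np.testing.assert_array_equal(despeckle(d), d)
        np.testing.assert_array_equal(fill_holes(f), f)
        assert not (m & ~f).any()  # fill never removes foreground
        if m.any():
            l = largest_component(m)
            np.testing.assert_array_equal(largest_component(l), l)
            assert not (l & ~m).any()  # never adds foreground


class TestMedianFilter:
    def test_constant_unchanged_and_hot_pixel_suppressed(self):
        const = np.full((8, 8), 9, dtype=np.uint16)
        np.testing.assert_array_equal(median_filter_2d(const, 1), const)
        hot = const.copy()
        hot[4, 4] = 60000
        assert median_filter_2d(hot, 1)[4, 4] == 9

    def test_matches_naive_windowed_median(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        np.testing.assert_array_equal(median_filter_2d(img, 1), median3_oracle(img))

    def test_radius_must_be_positive(self):
        with pytest.raises(ValueError):
            median_filter_2d(np.zeros((4, 4), dtype=np.uint8), 0)
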