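import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cytozone.quantify import (
    EmptyZoneError,
    bh_adjust,
    build_quant_tables,
    compare_groups,
    mean_pixel_intensity,
    mpi_ratio,
    pixel_correlation,
    pixel_correlation_detail,
)
from cytozone.segmentation import fov_structure_masks, segment_fov
from cytozone.zones import derive_zones, tissue_zones
from oracles import bh_oracle, mannwhitney_exact_oracle, mpi_oracle, pearson_oracle, wilcoxon_exact_oracle


class TestMPI:
    def test_constant_channel(self):
        ch = np.full((6, 6), 7, dtype=np.uint16)
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        assert mean_pixel_intensity(ch, mask) == 7.0

    def test_two_pixel_mean(self):
        ch = np.array([[1, 3]], dtype=np.uint16)
        assert mean_pixel_intensity(ch, np.array([[True, True]])) == 2.0

    def test_empty_zone_rejected(self):
        with pytest.raises(EmptyZoneError):
            mean_pixel_intensity(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_matches_naive_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ch = rng.integers(0, 1000, (8, 8))
        mask = rng.random((8, 8)) < 0.5
        if mask.any():
            assert mean_pixel_intensity(ch, mask) == pytest.approx(mpi_oracle(ch, mask))

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_union_mpi_is_area_weighted_mean(self, seed):
        rng = np.random.default_rng(seed)
        ch = rng.integers(0, 1000, (10, 10))
        a = rng.random((10, 10)) < 0.3
        b = (rng.random((10, 10)) < 0.3) & ~a
        if a.any() and b.any():
            na, nb = a.sum(), b.sum()
            expected = (na * mean_pixel_intensity(ch, a) + nb * mean_pixel_intensity(ch, b)) / (na + nb)
            assert mean_pixel_intensity(ch, a | b) == pytest.approx(expected)


class TestPixelCorrelation:
    def test_identical_channels_give_one(self):
        a = np.arange(36).reshape(6, 6)
        assert pixel_correlation(a, a) == pytest.approx(1.0)

    def test_complement_gives_minus_one(self):
        a = np.arange(36).reshape(6, 6)
        assert pixel_correlation(a, 100 - a) == pytest.approx(-1.0)

    def test_six_pixel_toy_matches_closed_form(self):
        a = np.array([[1, 4, 2], [8, 3, 5]], dtype=float)
        b = np.array([[2, 5, 1], [9, 2, 7]], dtype=float)
        assert pixel_correlation(a, b) == pytest.approx(pearson_oracle(a, b))

    def test_zero_variance_is_missing_with_reason(self):
        a = np.ones((4, 4))
        b = np.arange(16).reshape(4, 4)
        r, n, reason = pixel_correlation_detail(a, b)
        assert np.isnan(r) and reason == "zero variance" and n == 16

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(8)
        a = rng.random((10, 10))
        b = rng.random((10, 10))
        mask = rng.random((10, 10)) < 0.7
        r = pixel_correlation(a, b, mask)
        assert pixel_correlation(b, a, mask) == pytest.approx(r)
        assert pixel_correlation(3.5 * a + 11, b, mask) == pytest.approx(r)
        assert pixel_correlation(a, 0.2 * b - 4, mask) == pytest.approx(r)

    def test_scope_too_small_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            mask = np.zeros((4, 4), dtype=bool)
            mask[0, 0] = True
            pixel_correlation(np.ones((4, 4)), np.ones((4, 4)), mask)


class TestQuantTables:
    def test_row_counts_and_antibody_coloc_ordering(self, small_scene):
        fov, truth = small_scene
        masks = fov_structure_masks(fov)
        cells = segment_fov(fov)
        zonesets = [derive_zones(c, masks["cytoskeleton"], fov_id=fov.fov_id) for c in cells]
        quant, coloc = build_quant_tables(fov, zonesets)
        assert len(quant) == len(cells) * 5  # 5 canonical zones per cell
        # antibody is vimentin-weighted in the generator default mixture
        fov_rows = coloc[coloc.scope == "fov"].set_index("channel_pair")
        assert fov_rows.loc["antibodyxcytoskeleton", "r"] > fov_rows.loc["antibodyxnuclear", "r"]

    def test_tissue_mode_one_row_per_zone(self, small_scene):
        fov, _ = small_scene
        zs = tissue_zones(fov)
        quant, coloc = build_quant_tables(fov, [zs])
        assert len(quant) == 5
        assert (coloc[coloc.scope == "cell"].cell_id == 0).all()


class TestMpiRatio:
    def _table(self):
        import pandas as pd

        return pd.DataFrame({
            "fov_id": ["f"] * 6,
            "cell_id": [1, 1, 1, 2, 2, 2],
            "zone": ["nuc", "vim_hi", "vim_lo"] * 2,
            "area_px": [4, 6, 8, 4, 6, 8],
            "mpi": [5.0, 10.0, 2.0, 3.0, 3.0, 0.0],
            "reason": [None] * 6,
        })

    def test_identical_zone_gives_unity_and_simple_ratio(self):
        t = self._table()
        same = mpi_ratio(t, "nuc", "nuc")
        assert (same.ratio == 1.0).all()
        r = mpi_ratio(t, "vim_hi", "nuc")
        assert r.set_index("cell_id").loc[1, "ratio"] == pytest.approx(2.0)

    def test_zero_denominator_is_flagged_missing(self):
        r = mpi_ratio(self._table(), "nuc", "vim_lo").set_index("cell_id")
        assert np.isnan(r.loc[2, "ratio"]) and r.loc[2, "flag"] == "zero denominator"
        assert r.loc[1, "ratio"] == pytest.approx(5.0 / 2.0)

    def test_absent_zone_rejected(self):
        with pytest.raises(KeyError):
            mpi_ratio(self._table(), "nuc", "cytoplasm")


class TestGroupComparisons:
    def test_identical_paired_samples_give_p_one(self):
        x = [3.0, 1.0, 4.0, 1.0, 5.0]
        assert compare_groups(x, x, "wilcoxon_paired") == 1.0

    def test_mann_whitney_separated_triples_exact_p(self):
        assert compare_groups([1, 2, 3], [4, 5, 6], "mann_whitney") == pytest.approx(0.1)

    @given(seed=st.integers(0, 3000))
    @settings(max_examples=40, deadline=None)
    def test_exact_branch_matches_permutation_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
        x = rng.integers(0, 8, na).astype(float)  # integer values force ties
        y = rng.integers(0, 8, nb).astype(float)
        assert compare_groups(x, y, "mann_whitney") == pytest.approx(mannwhitney_exact_oracle(x, y))

    @given(seed=st.integers(0, 3000))
    @settings(max_examples=40, deadline=None)
    def test_wilcoxon_exact_matches_sign_flip_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        a = rng.integers(0, 10, n).astype(float)
        b = rng.integers(0, 10, n).astype(float)
        if not np.array_equal(a, b):
            assert compare_groups(a, b, "wilcoxon_paired") == pytest.approx(
                wilcoxon_exact_oracle(a - b)
            )

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.8, 1, 40)
        p = compare_groups(x, y, "mann_whitney")
        assert 0 < p < 0.05

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0], "mann_whitney")
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [2.0, 3.0, 4.0], "wilcoxon_paired")


class TestBHAdjust:
    def test_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_equal_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([0.04, 0.04, 0.04]), [0.04, 0.04, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    @given(seed=st.integers(0, 5000))
    @settings(max_examples=50, deadline=None)
    def test_matches_step_up_oracle_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(int(rng.integers(1, 12)))
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
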