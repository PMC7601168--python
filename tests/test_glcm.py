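import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fluortex.glcm import (
    FEATURE_COLUMNS,
    cooccurrence,
    extract_features,
    haralick,
)
from fluortex.imaging import GrayImage, LabelMask
from fluortex.quadtree import label_superpixels, quadtree_divide

from oracles import glcm_pairs, haralick_features


class TestCooccurrence:
    def test_two_row_window_by_hand(self):
        """[[0,0],[1,1]] at offset (0,1): the two horizontal pairs are
        (0,0) and (1,1); symmetric accumulation keeps the same support."""
        m = cooccurrence(np.array([[0, 0], [1, 1]], dtype=np.uint8))
        assert m.p[0, 0] == pytest.approx(0.5)
        assert m.p[1, 1] == pytest.approx(0.5)
        assert m.p.sum() == pytest.approx(1.0)
        assert np.count_nonzero(m.p) == 2

    def test_constant_window_single_entry(self):
        m = cooccurrence(np.full((8, 8), 42, dtype=np.uint8))
        assert m.p[42, 42] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)

    def test_matrix_is_256_by_256_without_requantization(self, rng):
        window = rng.integers(0, 256, size=(64, 64)).astype(np.uint8)
        m = cooccurrence(window)
        assert m.p.shape == (256, 256)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_pair_counter(self, seed):
        rng = np.random.default_rng(seed)
        window = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        m = cooccurrence(window)
        np.testing.assert_allclose(m.p, glcm_pairs(window), atol=1e-15)

    def test_symmetric_matrix_and_equal_marginal_moments(self, rng):
        window = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        m = cooccurrence(window, symmetric=True)
        np.testing.assert_allclose(m.p, m.p.T, atol=1e-15)
        assert m.mu_x == pytest.approx(m.mu_y)
        assert m.sigma_x == pytest.approx(m.sigma_y)
        assert m.p_sum.sum() == pytest.approx(1.0, abs=1e-12)
        assert m.p_diff.sum() == pytest.approx(1.0, abs=1e-12)

    def test_window_too_small_for_offset(self):
        with pytest.raises(ValueError, match="offset"):
            cooccurrence(np.zeros((3, 1), dtype=np.uint8), offset=(0, 1))

    def test_vertical_offset(self):
        m = cooccurrence(np.array([[0, 0], [1, 1]], dtype=np.uint8), offset=(1, 0))
        assert m.p[0, 1] == pytest.approx(0.5)
        assert m.p[1, 0] == pytest.approx(0.5)


class TestHaralick:
    def test_constant_window_degenerate(self):
        f = haralick(cooccurrence(np.full((8, 8), 99, dtype=np.uint8)))
        assert f.asm == pytest.approx(1.0)
        assert f.contrast == 0.0
        assert f.entropy == 0.0
        assert f.idm == pytest.approx(1.0)
        assert f.correlation == 0.0
        assert f.degenerate

    def test_checkerboard_by_hand(self):
        """{0,255} checkerboard: every horizontal pair is (0,255) or
        (255,0), so p has two 1/2 entries; contrast = 255^2."""
        tile = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        window = np.tile(tile, (4, 4))
        f = haralick(cooccurrence(window))
        assert f.contrast == pytest.approx(255.0**2)
        assert f.asm == pytest.approx(0.5)
        assert f.entropy == pytest.approx(np.log(2))

    @pytest.mark.parametrize("seed", range(10))
    def test_all_ten_features_match_literal_summation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        window = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        m = cooccurrence(window)
        ours = haralick(m)
        ref = haralick_features(m.p)
        for name in FEATURE_COLUMNS:
            assert getattr(ours, name) == pytest.approx(
                ref[name], rel=1e-10, abs=1e-12
            ), name

    def test_asm_bounds_and_entropy_bound(self, rng):
        window = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
        m = cooccurrence(window)
        f = haralick(m)
        assert 0 < f.asm <= 1
        assert f.entropy <= np.log(np.count_nonzero(m.p)) + 1e-12
        assert -1 <= f.correlation <= 1
        assert 0 < f.idm <= 1

    @settings(deadline=None, max_examples=15, derandomize=True)
    @given(seed=st.integers(0, 10_000), shift=st.integers(1, 40))
    def test_gray_level_shift_invariance(self, seed, shift):
        """Adding a constant (no clipping) leaves difference-based and
        entropy features unchanged and moves sum average by 2c."""
        rng = np.random.default_rng(seed)
        window = rng.integers(0, 256 - 40, size=(12, 12)).astype(np.uint8)
        f0 = haralick(cooccurrence(window))
        f1 = haralick(cooccurrence(window + shift))
        for name in ("asm", "contrast", "idm", "entropy", "difference_variance"):
            assert getattr(f1, name) == pytest.approx(getattr(f0, name), rel=1e-9)
        assert f1.sum_average == pytest.approx(f0.sum_average + 2 * shift, rel=1e-9)

    def test_transpose_with_reversed_offset_invariance(self, rng):
        window = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        f0 = haralick(cooccurrence(window, offset=(0, 1)))
        f1 = haralick(cooccurrence(window.T, offset=(1, 0)))
        for name in FEATURE_COLUMNS:
            assert getattr(f0, name) == pytest.approx(getattr(f1, name), rel=1e-10)

    def test_extra_features_finite_and_nonnegative_entropy(self, rng):
        window = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
        f = haralick(cooccurrence(window), extra=True)
        assert f.difference_entropy >= 0
        assert np.isfinite(f.info_correlation)


class TestExtractFeatures:
    def _labeled_grid(self, image, mask):
        grid = quadtree_divide(image, leaf_size=64)
        return label_superpixels(grid, LabelMask(mask))

    def test_one_row_per_valid_window(self, rng):
        image = GrayImage(rng.integers(0, 256, size=(128, 128)).astype(np.uint8))
        grid = self._labeled_grid(image, np.zeros((128, 128)))
        table = extract_features(image, grid)
        assert len(table) == 4
        assert set(FEATURE_COLUMNS) <= set(table.columns)

    def test_invalid_windows_excluded(self, rng):
        image = GrayImage(rng.integers(0, 256, size=(100, 100)).astype(np.uint8))
        grid = self._labeled_grid(image, np.zeros((100, 100)))
        table = extract_features(image, grid)
        assert len(table) == 1

    def test_empty_grid_warns(self):
        image = GrayImage(np.zeros((32, 32), dtype=np.uint8))
        grid = quadtree_divide(image, leaf_size=64)  # window overlaps padding
        with pytest.warns(UserWarning, match="no valid"):
            table = extract_features(image, grid)
        assert table.empty

    def test_lesion_windows_have_higher_contrast(self, default_scene):
        image, mask, _ = default_scene
        grid = self._labeled_grid(image, mask.labels)
        table = extract_features(image, grid)
        by_label = table.groupby("label")["contrast"].mean()
        assert by_label[1] > by_label[0]
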