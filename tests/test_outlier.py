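"""Densities, edge masks, density map, and the outlier-region loss."""

import math

import numpy as np
import pytest

from outlierloss import (
    EPS,
    LossConfig,
    bce_map,
    brute_force_window_count,
    density_black,
    density_map,
    density_white,
    edge_masks,
    edge_threshold,
    outlier_loss,
    outlier_loss_map,
)
from conftest import random_masks
from test_windows import isolated_block


def clamped(binary):
    return np.clip(np.asarray(binary, dtype=float), EPS, 1 - EPS)


class TestEdgeThreshold:
    @pytest.mark.parametrize("i,expected", [(1, 0), (3, 5), (5, 16), (7, 33)])
    def test_round_up_values(self, i, expected):
        assert edge_threshold(i) == expected

    def test_floor_variant(self):
        # floor(7/2) = 3 -> 49 - 9 = 40
        assert edge_threshold(7, rounding="floor") == 40

    def test_threshold_matches_block_corner_geometry(self):
        # the threshold IS the white gap count at the corner of an isolated
        # solid i x i block
        m = isolated_block(7)
        gw = (
            brute_force_window_count(m, 21) - brute_force_window_count(m, 7)
        )
        assert gw[40, 40] == edge_threshold(7)

    @pytest.mark.parametrize("i", [0, 2, -1])
    def test_invalid_i_rejected(self, i):
        with pytest.raises(ValueError):
            edge_threshold(i)


class TestDensities:
    def test_isolated_block_center(self):
        d = density_white(isolated_block(7))
        assert d[43, 43] == pytest.approx(50 / 393)

    def test_isolated_single_pixel(self):
        m = isolated_block(1)
        assert density_white(m)[40, 40] == pytest.approx(2 / 393)

    def test_all_black_interior(self):
        m = np.zeros((60, 60), dtype=np.int64)
        assert density_white(m)[30, 30] == pytest.approx(1 / 393)
        assert density_black(m)[30, 30] == pytest.approx(50.0)

    def test_densities_strictly_positive(self, rng):
        for mask in random_masks(rng, 5, shape=(30, 30)):
            assert (density_white(mask) > 0).all()
            assert (density_black(mask) > 0).all()

    def test_black_density_is_white_density_of_inverted_mask(self, rng):
        # interior only: black padding is asymmetric under inversion
        for mask in random_masks(rng, 5, shape=(30, 30)):
            np.testing.assert_allclose(
                density_black(mask)[10:-10, 10:-10],
                density_white(1 - mask)[10:-10, 10:-10],
            )


class TestEdgeMasks:
    def test_block_corner_is_boundary_case_and_retained(self):
        mw, _ = edge_masks(isolated_block(7))
        assert mw[40, 40] == 1  # gap_white == 33, not > 33

    def test_large_block_interior_excluded(self):
        mw, _ = edge_masks(isolated_block(28))
        assert mw[53, 53] == 0  # center: gap_white = 441 - 49 = 392 > 33

    def test_all_zero_image(self):
        mw, mb = edge_masks(np.zeros((50, 50)))
        assert (mw == 1).all()
        assert (mb == 0).all()  # gap_black = 392 > 33 everywhere


class TestDensityMap:
    def test_nonnegative_and_zero_where_masked(self, rng):
        for mask in random_masks(rng, 5, shape=(40, 40)):
            dmap = density_map(clamped(mask))
            assert (dmap >= 0).all()
            mw, mb = edge_masks(mask)
            selected = np.where(mask == 1, mw, mb)
            assert (dmap[selected == 0] == 0).all()

    def test_large_block_fully_zero(self):
        # solid foreground with both sides >= j is never treated as noise
        m = np.zeros((70, 70), dtype=np.int64)
        m[20:45, 20:45] = 1
        assert (density_map(clamped(m)) == 0).all()

    def test_isolated_block_center_value(self):
        dmap = density_map(clamped(isolated_block(7)))
        assert dmap[43, 43] == pytest.approx(50 / 393)

    def test_all_half_input_binarizes_to_white(self):
        # tie-break: 0.5 rounds to white, so the map follows all-white geometry
        pred = np.full((50, 50), 0.5)
        ref = density_map(clamped(np.ones((50, 50), dtype=np.int64)))
        np.testing.assert_allclose(density_map(pred), ref)

    def test_monotone_in_blob_size_at_center(self):
        # growing an isolated centered blob does not decrease center density
        prev = -np.inf
        for size in (1, 3, 5, 7):
            dmap = density_map(clamped(isolated_block(size, at=(40, 40))))
            center = 40 + size // 2
            val = dmap[center, center]
            assert val >= prev
            prev = val

    def test_translation_equivariance(self):
        a = isolated_block(5, at=(30, 30))
        b = isolated_block(5, at=(36, 41))
        da, db = density_map(clamped(a)), density_map(clamped(b))
        np.testing.assert_allclose(da[20:46, 20:46], db[26:52, 31:57])

    def test_out_of_range_prediction_rejected(self):
        with pytest.raises(ValueError):
            density_map(np.full((10, 10), 1.5))


class TestOutlierLoss:
    def test_loss_map_is_bce_minus_density(self, rng):
        mask = random_masks(rng, 1, shape=(40, 40))[0]
        pred = clamped(mask)
        np.testing.assert_allclose(
            outlier_loss_map(pred, mask),
            bce_map(pred, mask) - density_map(pred),
        )

    def test_perfect_all_background_prediction_is_near_zero(self):
        m = np.zeros((100, 100), dtype=np.int64)
        assert abs(outlier_loss(clamped(m), m)) < 1e-4

    def test_uniform_half_prediction_bce_term(self):
        label = np.zeros((50, 50), dtype=np.int64)
        pred = np.full((50, 50), 0.5)
        lmap = outlier_loss_map(pred, label) + density_map(pred)
        np.testing.assert_allclose(lmap, math.log(2), rtol=1e-12)

    def test_loss_equals_bce_where_density_zero(self):
        m = np.zeros((70, 70), dtype=np.int64)
        m[20:45, 20:45] = 1  # large block: density map identically zero
        pred = clamped(m)
        np.testing.assert_allclose(outlier_loss_map(pred, m), bce_map(pred, m))

    def test_sum_is_area_times_mean(self, figure9):
        mask, _ = figure9
        pred = clamped(mask)
        s = outlier_loss(pred, mask, reduction="sum")
        mn = outlier_loss(pred, mask, reduction="mean")
        assert s == pytest.approx(mask.size * mn)

    def test_figure9_self_prediction_is_negative(self, figure9):
        mask, _ = figure9
        assert outlier_loss(clamped(mask), mask) < 0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            outlier_loss_map(np.full((5, 5), 0.5), np.zeros((6, 6)))

    def test_unknown_reduction_rejected(self):
        m = np.zeros((10, 10), dtype=np.int64)
        with pytest.raises(ValueError):
            outlier_loss(clamped(m), m, reduction="median")


class TestLossConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"i": 4},
            {"i": 0},
            {"j": 5},        # j <= i
            {"j": 22},       # even
            {"smooth": 0.0},
            {"alpha": -1.0},
            {"reduction": "max"},
            {"threshold_rounding": "trunc"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LossConfig(**kwargs)
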