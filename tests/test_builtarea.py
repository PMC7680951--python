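"""Built-mask binarization, presence resampling, union, distance-to-edge."""

import numpy as np
import pytest

import dasypop as dp
from dasypop.builtarea import MASK_NODATA, BuiltMask
from dasypop.errors import AlignmentError, UndefinedDistanceError, ValidationError
from dasypop.geoio import GridSpec, Raster

from conftest import planar_grid


def _mask_from(arr, cell=100.0) -> BuiltMask:
    arr = np.asarray(arr, dtype=np.uint8)
    grid = planar_grid(*arr.shape, cell)
    return BuiltMask(Raster(grid, arr, nodata=MASK_NODATA))


class TestBinarize:
    def test_categorical_class_rule(self):
        grid = planar_grid(2, 2)
        rast = Raster(grid, np.array([[190, 10], [190, 210]]), nodata=-1)
        mask = dp.binarize(rast, classes=[190])
        np.testing.assert_array_equal(mask.raster.values, [[1, 0], [1, 0]])

    def test_absent_class_rejected(self):
        grid = planar_grid(2, 2)
        rast = Raster(grid, np.zeros((2, 2)), nodata=-1)
        with pytest.raises(ValidationError):
            dp.binarize(rast, classes=[190])

    def test_all_zero_raster_gives_all_zero_mask(self):
        grid = planar_grid(3, 3)
        mask = dp.binarize(Raster(grid, np.zeros((3, 3)), nodata=-1), threshold=0.5)
        assert mask.built_count() == 0

    def test_threshold_matches_elementwise_comparison(self):
        rng = np.random.default_rng(1)
        vals = rng.random((3, 3))
        grid = planar_grid(3, 3)
        mask = dp.binarize(Raster(grid, vals, nodata=-1), threshold=0.5)
        np.testing.assert_array_equal(mask.raster.values, (vals >= 0.5).astype(np.uint8))

    def test_nodata_preserved(self):
        grid = planar_grid(2, 2)
        vals = np.array([[np.nan, 0.8], [0.2, 0.9]])
        mask = dp.binarize(Raster(grid, vals), threshold=0.5)
        assert mask.raster.values[0, 0] == MASK_NODATA
        assert mask.raster.values[0, 1] == 1


class TestResamplePresence:
    def test_single_built_fine_cell_marks_coarse_cell(self):
        fine = _mask_from([[1, 0], [0, 0]], cell=50.0)
        target = planar_grid(1, 1, 100.0)
        out = dp.resample_presence(fine, target)
        assert out.raster.values[0, 0] == 1

    def test_all_zero_stays_all_zero(self):
        fine = _mask_from(np.zeros((8, 8)), cell=25.0)
        out = dp.resample_presence(fine, planar_grid(2, 2, 100.0))
        assert out.built_count() == 0
        assert (out.raster.values == 0).all()

    def test_integer_factor_matches_blockwise_any(self):
        rng = np.random.default_rng(7)
        fine_arr = (rng.random((20, 20)) < 0.2).astype(np.uint8)
        fine = _mask_from(fine_arr, cell=25.0)
        out = dp.resample_presence(fine, planar_grid(5, 5, 100.0))
        expected = fine_arr.reshape(5, 4, 5, 4).any(axis=(1, 3)).astype(np.uint8)
        np.testing.assert_array_equal(out.raster.values, expected)

    def test_partial_overlap_counts_as_covering(self):
        # three fine cells of 2 m onto two coarse cells of 3 m: the middle
        # fine cell straddles both coarse cells
        fine_grid = GridSpec(0.0, 2.0, 2.0, 1, 3, "planar:test")
        coarse = GridSpec(0.0, 3.0, 3.0, 1, 2, "planar:test")
        mid = BuiltMask(Raster(fine_grid, np.array([[0, 1, 0]], np.uint8), nodata=255))
        out = dp.resample_presence(mid, coarse)
        np.testing.assert_array_equal(out.raster.values, [[1, 1]])
        left = BuiltMask(Raster(fine_grid, np.array([[1, 0, 0]], np.uint8), nodata=255))
        out = dp.resample_presence(left, coarse)
        np.testing.assert_array_equal(out.raster.values, [[1, 0]])

    def test_coarse_zero_only_where_all_fine_zero(self):
        rng = np.random.default_rng(3)
        fine_arr = (rng.random((12, 12)) < 0.15).astype(np.uint8)
        fine = _mask_from(fine_arr, cell=100.0 / 3.0)
        out = dp.resample_presence(fine, planar_grid(4, 4, 100.0))
        blocks = fine_arr.reshape(4, 3, 4, 3)
        for r in range(4):
            for c in range(4):
                if out.raster.values[r, c] == 0:
                    assert blocks[r, :, c, :].sum() == 0

    def test_coarser_native_grid_rejected(self):
        coarse = _mask_from(np.ones((2, 2)), cell=200.0)
        with pytest.raises(ValidationError):
            dp.resample_presence(coarse, planar_grid(4, 4, 100.0))


class TestCombineMasks:
    def test_union_with_zeros_is_identity(self):
        rng = np.random.default_rng(0)
        a = _mask_from((rng.random((6, 6)) < 0.3).astype(np.uint8))
        z = _mask_from(np.zeros((6, 6)))
        out = dp.combine_masks([a, z])
        np.testing.assert_array_equal(out.built, a.built)
        assert out.source_tag == "COMBO"

    def test_three_disjoint_cells(self):
        arrs = []
        for i in range(3):
            arr = np.zeros((3, 3), np.uint8)
            arr[i, i] = 1
            arrs.append(_mask_from(arr))
        assert dp.combine_masks(arrs).built_count() == 3

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_union_algebra_on_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (
            _mask_from((rng.random((8, 8)) < 0.3).astype(np.uint8)) for _ in range(3)
        )
        ab = dp.combine_masks([a, b]).built
        ba = dp.combine_masks([b, a]).built
        np.testing.assert_array_equal(ab, ba)  # commutative
        abc1 = dp.combine_masks([dp.combine_masks([a, b]), c]).built
        abc2 = dp.combine_masks([a, dp.combine_masks([b, c])]).built
        np.testing.assert_array_equal(abc1, abc2)  # associative
        aa = dp.combine_masks([a, a]).built
        np.testing.assert_array_equal(aa, a.built)  # idempotent
        # monotone: the union has at least as many built cells as any member
        assert dp.combine_masks([a, b, c]).built_count() >= max(
            a.built_count(), b.built_count(), c.built_count()
        )

    def test_misaligned_masks_rejected(self):
        a = _mask_from(np.zeros((3, 3)))
        b = _mask_from(np.zeros((4, 4)))
        with pytest.raises(AlignmentError):
            dp.combine_masks([a, b])


def _brute_force_signed_distance(arr, cell_m):
    """O(n^2) nearest-opposite-class distance with an interior minus sign."""
    rows, cols = arr.shape
    out = np.zeros(arr.shape)
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    for r, c in cells:
        opposite = [(r2, c2) for r2, c2 in cells if arr[r2, c2] != arr[r, c]]
        d = min(np.hypot(r - r2, c - c2) for r2, c2 in opposite) * cell_m
        out[r, c] = -d if arr[r, c] else d
    return out


class TestDistanceToEdge:
    def test_adjacent_cell_of_single_built_cell(self):
        arr = np.zeros((3, 3), np.uint8)
        arr[1, 1] = 1
        surf = dp.distance_to_edge(_mask_from(arr))
        assert surf.raster.values[1, 2] == pytest.approx(100.0)
        assert surf.raster.values[0, 0] == pytest.approx(100.0 * np.sqrt(2))

    def test_single_cell_feature_interior_value(self):
        arr = np.zeros((3, 3), np.uint8)
        arr[1, 1] = 1
        surf = dp.distance_to_edge(_mask_from(arr))
        v = surf.raster.values[1, 1]
        assert v < 0 and abs(v) <= 100.0

    def test_matches_brute_force_on_random_9x9(self):
        rng = np.random.default_rng(5)
        arr = (rng.random((9, 9)) < 0.4).astype(np.uint8)
        assert arr.any() and not arr.all()
        surf = dp.distance_to_edge(_mask_from(arr))
        np.testing.assert_allclose(
            surf.raster.values, _brute_force_signed_distance(arr, 100.0), rtol=1e-12
        )

    def test_sign_flips_exactly_across_boundary(self):
        rng = np.random.default_rng(8)
        arr = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        surf = dp.distance_to_edge(_mask_from(arr))
        vals = surf.raster.values
        assert (vals[arr == 1] < 0).all()
        assert (vals[arr == 0] > 0).all()

    def test_lipschitz_between_adjacent_cells(self):
        rng = np.random.default_rng(9)
        arr = (rng.random((15, 15)) < 0.25).astype(np.uint8)
        vals = np.abs(dp.distance_to_edge(_mask_from(arr)).raster.values)
        step = 100.0 * np.sqrt(2) + 1e-9
        assert np.all(np.abs(np.diff(vals, axis=0)) <= step)
        assert np.all(np.abs(np.diff(vals, axis=1)) <= step)

    def test_uniform_mask_rejected(self):
        with pytest.raises(UndefinedDistanceError):
            dp.distance_to_edge(_mask_from(np.ones((4, 4))))
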