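import numpy as np
import pytest

from landchange.classification import (
    ClassifierSpec,
    fill_gaps,
    majority_filter,
    postprocess_chain,
    reassign_elevation_band,
    sample_training_pixels,
    train_classify,
)
from landchange.grids import (
    CovariateStack,
    GridTransform,
    LandCoverGrid,
    PixelPolygon,
)


def _stack(shape=(12, 12)):
    rng = np.random.default_rng(0)
    return CovariateStack(
        layers={"a": rng.random(shape), "b": rng.random(shape)},
        transform=GridTransform(),
    )


def _block_polygon(r0, c0, h, w, code, pid=0):
    rr, cc = np.meshgrid(np.arange(r0, r0 + h), np.arange(c0, c0 + w), indexing="ij")
    return PixelPolygon(class_code=code, cells=np.column_stack([rr.ravel(), cc.ravel()]), pid=pid)


class TestSampling:
    def test_large_polygon_capped_at_30(self):
        stack = _stack()
        poly = _block_polygon(0, 0, 10, 10, code=3)
        sample = sample_training_pixels([poly], stack, per_polygon=30, seed=0)
        assert sample.n == 30
        assert len({(r, c) for r, c in zip(sample.rows, sample.cols)}) == 30  # no replacement

    def test_small_polygon_exhausted(self):
        stack = _stack()
        poly = _block_polygon(0, 0, 2, 5, code=3)
        sample = sample_training_pixels([poly], stack, per_polygon=30, seed=0)
        assert sample.n == 10

    def test_seeded_determinism(self):
        stack = _stack()
        polys = [_block_polygon(0, 0, 6, 6, 3, 0), _block_polygon(6, 6, 6, 6, 5, 1)]
        a = sample_training_pixels(polys, stack, seed=4)
        b = sample_training_pixels(polys, stack, seed=4)
        np.testing.assert_array_equal(a.rows, b.rows)
        np.testing.assert_array_equal(a.X, b.X)

    def test_polygon_outside_raster_rejected(self):
        stack = _stack((5, 5))
        poly = _block_polygon(3, 3, 4, 4, code=3)
        with pytest.raises(ValueError, match="outside"):
            sample_training_pixels([poly], stack)


class TestTrainClassify:
    def test_separable_classes_recovered(self):
        # class 3 on the west half, class 5 on the east; layer a separates them
        rng = np.random.default_rng(1)
        cols = np.tile(np.arange(20.0), (20, 1))
        stack = CovariateStack(layers={"a": cols, "b": rng.random((20, 20))},
                               transform=GridTransform())
        truth = np.where(cols < 10, 3, 5).astype(np.int32)
        polys = [
            _block_polygon(2, 1, 6, 6, 3, 0),
            _block_polygon(12, 2, 6, 6, 3, 1),
            _block_polygon(2, 13, 6, 6, 5, 2),
            _block_polygon(12, 12, 6, 6, 5, 3),
        ]
        sample = sample_training_pixels(polys, stack, seed=0)
        grid = train_classify(sample, ClassifierSpec(n_trees=100, seed=0), stack)
        acc = (grid.values == truth).mean()
        assert acc > 0.99

    def test_predictions_within_label_set(self):
        stack = _stack()
        polys = [_block_polygon(0, 0, 4, 4, 3, 0), _block_polygon(8, 8, 4, 4, 5, 1)]
        sample = sample_training_pixels(polys, stack, seed=0)
        grid = train_classify(sample, ClassifierSpec(n_trees=20, seed=0), stack)
        assert set(np.unique(grid.values)) <= {3, 5}

    def test_seeded_determinism(self):
        stack = _stack()
        polys = [_block_polygon(0, 0, 4, 4, 3, 0), _block_polygon(8, 8, 4, 4, 5, 1)]
        sample = sample_training_pixels(polys, stack, seed=0)
        spec = ClassifierSpec(n_trees=30, seed=7)
        a = train_classify(sample, spec, stack)
        b = train_classify(sample, spec, stack)
        np.testing.assert_array_equal(a.values, b.values)

    def test_single_class_rejected(self):
        stack = _stack()
        sample = sample_training_pixels([_block_polygon(0, 0, 4, 4, 3)], stack, seed=0)
        with pytest.raises(ValueError, match="2 classes"):
            train_classify(sample, ClassifierSpec(n_trees=10), stack)

    def test_nodata_where_predictor_nan(self):
        rng = np.random.default_rng(2)
        layers = {"a": rng.random((10, 10)), "b": rng.random((10, 10))}
        layers["a"][0, 0] = np.nan
        stack = CovariateStack(layers=layers, transform=GridTransform())
        polys = [_block_polygon(2, 2, 3, 3, 3, 0), _block_polygon(6, 6, 3, 3, 5, 1)]
        sample = sample_training_pixels(polys, stack, seed=0)
        grid = train_classify(sample, ClassifierSpec(n_trees=10, seed=0), stack)
        assert grid.values[0, 0] == grid.nodata


class TestClassifierSpec:
    def test_defaults_match_contract(self):
        spec = ClassifierSpec()
        assert spec.n_trees == 500
        assert spec.bag_fraction == pytest.approx(2 / 3)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            ClassifierSpec(n_trees=0)
        with pytest.raises(ValueError):
            ClassifierSpec(bag_fraction=1.5)


class TestFillGaps:
    def _grids(self):
        transform = GridTransform()
        primary = LandCoverGrid(np.array([[3, 0], [0, 5]], dtype=np.int32), transform=transform)
        secondary = LandCoverGrid(np.array([[4, 5], [0, 4]], dtype=np.int32), transform=transform)
        return primary, secondary

    def test_primary_valid_untouched(self):
        primary, secondary = self._grids()
        out = fill_gaps(primary, secondary)
        assert out.values[0, 0] == 3
        assert out.values[1, 1] == 5

    def test_gap_filled_from_secondary(self):
        primary, secondary = self._grids()
        assert fill_gaps(primary, secondary).values[0, 1] == 5

    def test_both_nodata_stays_nodata(self):
        primary, secondary = self._grids()
        assert fill_gaps(primary, secondary).values[1, 0] == 0

    def test_nodata_never_increases(self):
        primary, secondary = self._grids()
        out = fill_gaps(primary, secondary)
        assert (~out.valid_mask).sum() <= (~primary.valid_mask).sum()

    def test_misaligned_rejected(self):
        primary, _ = self._grids()
        other = LandCoverGrid(np.ones((3, 3), dtype=np.int32), transform=GridTransform())
        with pytest.raises(ValueError, match="misaligned"):
            fill_gaps(primary, other)


class TestReassignElevationBand:
    def test_wrong_band_reassigned(self):
        grid = LandCoverGrid(np.array([[5]], dtype=np.int32))  # forest < 600 m label
        out = reassign_elevation_band(grid, np.array([[1200.0]]))
        assert out.values[0, 0] == 4  # 600-1,800 m band

    def test_correct_band_unchanged(self):
        grid = LandCoverGrid(np.array([[4]], dtype=np.int32))
        assert reassign_elevation_band(grid, np.array([[900.0]])).values[0, 0] == 4

    def test_high_elevation_becomes_fir_band(self):
        grid = LandCoverGrid(np.array([[3]], dtype=np.int32))
        assert reassign_elevation_band(grid, np.array([[2700.0]])).values[0, 0] == 2

    def test_non_forest_untouched(self):
        grid = LandCoverGrid(np.array([[10]], dtype=np.int32))  # paddyfield
        assert reassign_elevation_band(grid, np.array([[2000.0]])).values[0, 0] == 10

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        values = rng.choice([2, 3, 4, 5, 10, 13], size=(15, 15)).astype(np.int32)
        dem = rng.random((15, 15)) * 4000
        grid = LandCoverGrid(values)
        once = reassign_elevation_band(grid, dem)
        twice = reassign_elevation_band(once, dem)
        np.testing.assert_array_equal(once.values, twice.values)


class TestMajorityFilter:
    def test_constant_grid_fixed_point(self):
        grid = LandCoverGrid(np.full((6, 6), 3, dtype=np.int32))
        np.testing.assert_array_equal(majority_filter(grid).values, grid.values)

    def test_isolated_cell_smoothed(self):
        values = np.full((3, 3), 3, dtype=np.int32)
        values[1, 1] = 11
        out = majority_filter(LandCoverGrid(values))
        assert out.values[1, 1] == 3

    def test_tie_with_center_retains_center(self):
        # 3x3 corner block: 4 cells of class 3 incl. center vs 4 of class 5
        values = np.array([[3, 3, 5], [3, 3, 5], [5, 5, 1]], dtype=np.int32)
        out = majority_filter(LandCoverGrid(values))
        assert out.values[1, 1] == 3

    def test_tie_without_center_takes_smallest_code(self):
        values = np.array([[4, 4, 0], [5, 3, 0], [5, 0, 0]], dtype=np.int32)
        # window of (1,1): {4:2, 5:2, 3:1} -> tie 4 vs 5 excludes center class 3
        out = majority_filter(LandCoverGrid(values))
        assert out.values[1, 1] == 4

    def test_nodata_excluded_and_preserved(self):
        values = np.array([[0, 3, 3], [0, 3, 3], [0, 0, 0]], dtype=np.int32)
        out = majority_filter(LandCoverGrid(values))
        assert out.values[0, 0] == 0
        assert out.values[0, 1] == 3

    def test_checkerboard_deterministic(self):
        values = np.indices((6, 6)).sum(axis=0) % 2
        values = np.where(values == 0, 3, 5).astype(np.int32)
        grid = LandCoverGrid(values)
        a = majority_filter(grid)
        b = majority_filter(grid)
        np.testing.assert_array_equal(a.values, b.values)


class TestFullChain:
    def test_chain_recovers_true_labels(self):
        """classify -> fill -> reassign -> filter recovers >= 95% of epoch-1
        truth when class supports are separable from the covariates."""
        from landchange.synthetic import ScenarioConfig, apply_cloud_mask, generate_scene_pair

        # degradation off: every class is a deterministic function of
        # elevation, slope and the village/river distance layers
        cfg = ScenarioConfig(shape=(100, 100), seed=19, n_villages=2,
                             degradation_intensity=0.0, cloud_fraction=0.15)
        scene = generate_scene_pair(cfg)
        stack = scene.covariates
        names = ("elevation", "slope", "dist_village", "dist_river")
        sample = sample_training_pixels(scene.polygons["training"], stack, seed=0,
                                        predictor_names=names)
        spec = ClassifierSpec(n_trees=100, seed=0)
        primary = train_classify(sample, spec, stack, epoch="t1")
        primary = apply_cloud_mask(primary, scene.cloud_mask)
        secondary = train_classify(
            sample_training_pixels(scene.polygons["training"], stack, seed=1,
                                   predictor_names=("elevation", "slope", "dist_river")),
            ClassifierSpec(n_trees=100, seed=1), stack, epoch="t1",
        )
        final = postprocess_chain(primary, secondary, stack.layers["elevation"])
        agree = (final.values == scene.epoch1.values).mean()
        assert agree >= 0.95
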