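"""Supervised classification stage and bespoke post-processing.

The classifier itself is a standard random-forest ensemble (500 trees,
2/3 bootstrap per tree, sqrt(p) candidate predictors per split).  The
post-processing chain — gap filling from a secondary map, elevation-band
reassignment of forest labels, and a single-pass 3x3 majority filter — is
applied in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .grids import (
    CovariateStack,
    LandCoverGrid,
    PixelPolygon,
    assert_aligned,
    forest_class_for_elevation,
)

__all__ = [
    "TrainingSample",
    "ClassifierSpec",
    "sample_training_pixels",
    "train_classify",
    "fill_gaps",
    "reassign_elevation_band",
    "majority_filter",
    "postprocess_chain",
]

FOREST_BAND_CODES = (2, 3, 4, 5)


@dataclass
class TrainingSample:
    rows: np.ndarray
    cols: np.ndarray
    X: np.ndarray  # (n, p) predictor matrix
    labels: np.ndarray  # class codes
    polygon_ids: np.ndarray
    predictor_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.labels.shape[0]


@dataclass(frozen=True)
class ClassifierSpec:
    """Random-forest ensemble parameters."""

    n_trees: int = 500
    bag_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not (0.0 < self.bag_fraction <= 1.0):
            raise ValueError("bag_fraction must be in (0, 1]")


def sample_training_pixels(
    polygons: list[PixelPolygon],
    stack: CovariateStack,
    per_polygon: int = 30,
    seed: int = 0,
    predictor_names: tuple[str, ...] | None = None,
) -> TrainingSample:
    """Sample up to *per_polygon* cells from each polygon without replacement."""
    rng = np.random.default_rng(seed)
    names = predictor_names or stack.names
    rows_all, cols_all, labels, pids = [], [], [], []
    n_rows, n_cols = stack.shape
    for p in polygons:
        if (p.cells[:, 0] >= n_rows).any() or (p.cells[:, 1] >= n_cols).any():
            raise ValueError(f"polygon {p.pid} extends outside the raster")
        k = min(per_polygon, p.n_cells)
        take = rng.choice(p.n_cells, size=k, replace=False)
        rows_all.append(p.cells[take, 0])
        cols_all.append(p.cells[take, 1])
        labels.append(np.full(k, p.class_code, dtype=np.int32))
        pids.append(np.full(k, p.pid, dtype=np.int32))
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    return TrainingSample(
        rows=rows,
        cols=cols,
        X=stack.table(rows, cols, names),
        labels=np.concatenate(labels),
        polygon_ids=np.concatenate(pids),
        predictor_names=tuple(names),
    )


def train_classify(
    sample: TrainingSample,
    spec: ClassifierSpec,
    stack: CovariateStack,
    epoch: str | None = None,
    scheme=None,
) -> LandCoverGrid:
    """Fit the ensemble on *sample* and predict a class map over all cells
    where every predictor is finite; other cells become nodata."""
    from .grids import DEFAULT_SCHEME

    scheme = scheme or DEFAULT_SCHEME
    if np.unique(sample.labels).size < 2:
        raise ValueError("training sample must contain at least 2 classes")
    clf = RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features="sqrt",
        bootstrap=True,
        max_samples=spec.bag_fraction,
        random_state=spec.seed,
        n_jobs=1,
    )
    clf.fit(sample.X, sample.labels)

    n_rows, n_cols = stack.shape
    rr, cc = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    X_all = stack.table(rr.ravel(), cc.ravel(), sample.predictor_names)
    valid = np.isfinite(X_all).all(axis=1)
    predicted = np.zeros(n_rows * n_cols, dtype=np.int32)
    if valid.any():
        predicted[valid] = clf.predict(X_all[valid])
    return LandCoverGrid(
        values=predicted.reshape(n_rows, n_cols),
        scheme=scheme,
        nodata=0,
        transform=stack.transform,
        epoch=epoch,
    )


def fill_gaps(primary: LandCoverGrid, secondary: LandCoverGrid) -> LandCoverGrid:
    """Fill primary nodata cells from the secondary classification.

    Valid primary cells are never overwritten.
    """
    check = assert_aligned([primary, secondary])
    if not check:
        raise ValueError(f"misaligned inputs: {check.message}")
    values = primary.values.copy()
    gaps = ~primary.valid_mask & secondary.valid_mask
    values[gaps] = secondary.values[gaps]
    return primary.copy_with(values)


def reassign_elevation_band(grid: LandCoverGrid, dem: np.ndarray) -> LandCoverGrid:
    """Relabel forest cells whose class band disagrees with the DEM band.

    Only the four forest-band classes participate; all other classes pass
    through untouched.  Idempotent by construction.
    """
    dem = np.asarray(dem, dtype=float)
    if dem.shape != grid.shape:
        raise ValueError(f"DEM shape {dem.shape} != grid shape {grid.shape}")
    values = grid.values.copy()
    forest = np.isin(values, FOREST_BAND_CODES)
    correct = forest_class_for_elevation(dem)
    values[forest] = correct[forest]
    return grid.copy_with(values)


def majority_filter(grid: LandCoverGrid) -> LandCoverGrid:
    """Single-pass 3x3 modal smoothing.

    Nodata cells neither vote nor change.  Ties keep the center's class when
    it participates in the tie; otherwise the smallest code wins.  Border
    cells use truncated neighbourhoods.
    """
    values = grid.values
    valid = grid.valid_mask
    kernel = np.ones((3, 3))
    codes = np.array(sorted(grid.scheme.codes))
    counts = np.empty((codes.size,) + values.shape, dtype=np.int32)
    for i, code in enumerate(codes):
        member = ((values == code) & valid).astype(np.int32)
        counts[i] = ndimage.correlate(member, kernel.astype(np.int32), mode="constant", cval=0)
    best = counts.max(axis=0)
    # smallest code attaining the max (codes ascending, argmax takes first)
    winner = codes[np.argmax(counts, axis=0)]
    # center retained when its own class ties the max
    center_idx = np.searchsorted(codes, values.clip(codes.min(), codes.max()))
    center_count = np.take_along_axis(counts, center_idx[None, ...], axis=0)[0]
    keep_center = valid & (center_count == best)
    out = np.where(keep_center, values, winner).astype(values.dtype)
    out[~valid] = grid.nodata
    out[best == 0] = grid.nodata  # all-nodata neighbourhood
    return grid.copy_with(out)


def postprocess_chain(
    primary: LandCoverGrid, secondary: LandCoverGrid | None, dem: np.ndarray
) -> LandCoverGrid:
    """fill gaps -> elevation-band reassignment -> majority filter."""
    out = fill_gaps(primary, secondary) if secondary is not None else primary
    out = reassign_elevation_band(out, dem)
    return majority_filter(out)
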