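"""Core raster data model and GeoTIFF/GeoJSON I/O shared by all pipeline stages.

The raster model is deliberately small: a 2-D array, a class scheme, a nodata
code and an affine georeference restricted to north-up, square-ish cells
(row 0 is the northernmost row; coordinates refer to cell centers).  GeoTIFF
files are written through :mod:`tifffile` with the standard georeferencing
tags (``ModelPixelScaleTag``, ``ModelTiepointTag``, ``GDAL_NODATA``) so that
outputs open in any GIS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import tifffile
from shapely.geometry import box, mapping
from shapely.ops import unary_union

__all__ = [
    "GridTransform",
    "ClassScheme",
    "LandCoverGrid",
    "CovariateStack",
    "PixelPolygon",
    "AlignmentCheck",
    "DEFAULT_SCHEME",
    "CATEGORY_SCHEME",
    "CATEGORIES",
    "BAND_EDGES",
    "assert_aligned",
    "read_landcover",
    "write_landcover",
    "read_raster",
    "write_raster",
    "write_polygons",
    "read_polygons",
    "forest_class_for_elevation",
]

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

#: Elevation thresholds (m) separating the forest/alpine bands.
BAND_EDGES = (600.0, 1800.0, 2500.0, 3000.0)

CATEGORIES = ("alpine", "forest", "shrubland", "agriculture_developed", "other")


@dataclass(frozen=True)
class GridTransform:
    """North-up affine georeference: top-left corner and cell size in meters."""

    x0: float = 0.0
    y0: float = 0.0
    dx: float = 30.0
    dy: float = 30.0

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell size must be positive")

    @property
    def cell_area_ha(self) -> float:
        return self.dx * self.dy / 10_000.0

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (self.x0 + (col + 0.5) * self.dx, self.y0 - (row + 0.5) * self.dy)

    def cell_box(self, row: int, col: int):
        """Shapely box covering one cell (used for polygon export)."""
        x = self.x0 + col * self.dx
        y = self.y0 - row * self.dy
        return box(x, y - self.dy, x + self.dx, y)

    def close_to(self, other: "GridTransform", tol: float = 1e-6) -> bool:
        return (
            abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.dx - other.dx) <= tol
            and abs(self.dy - other.dy) <= tol
        )


@dataclass(frozen=True)
class ClassScheme:
    """Integer class codes, display names and a total code -> category map."""

    codes: tuple[int, ...]
    names: tuple[str, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("class codes must be unique")
        if not (len(self.codes) == len(self.names) == len(self.categories)):
            raise ValueError("codes, names and categories must align")
        bad = set(self.categories) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")

    @property
    def category_map(self) -> dict[int, str]:
        return dict(zip(self.codes, self.categories))

    def name_of(self, code: int) -> str:
        return self.names[self.codes.index(code)]

    def codes_for_category(self, category: str) -> tuple[int, ...]:
        return tuple(c for c, cat in zip(self.codes, self.categories) if cat == category)

    def contains(self, codes: np.ndarray) -> np.ndarray:
        return np.isin(codes, self.codes)

    def to_config(self) -> list[dict]:
        return [
            {"code": c, "name": n, "category": cat}
            for c, n, cat in zip(self.codes, self.names, self.categories)
        ]

    @classmethod
    def from_config(cls, entries: Sequence[Mapping]) -> "ClassScheme":
        return cls(
            codes=tuple(int(e["code"]) for e in entries),
            names=tuple(str(e["name"]) for e in entries),
            categories=tuple(str(e["category"]) for e in entries),
        )


#: 15-class land-cover scheme: elevation-banded forest, degraded woody
#: vegetation, agriculture/developed classes and non-vegetated residuals.
DEFAULT_SCHEME = ClassScheme(
    codes=tuple(range(1, 16)),
    names=(
        "Alpine vegetation",
        "Fir/Rhododendron",
        "Forest > 1,800 m",
        "Forest 600-1,800 m",
        "Forest < 600 m",
        "Secondary forest 600-1,800 m",
        "Secondary forest < 600 m",
        "Shrub/Bush",
        "Grassland/Pasture",
        "Paddyfield",
        "Clearcut",
        "Settlement",
        "Rock/Boulder",
        "Snow/Glacier",
        "Streambed/Water",
    ),
    categories=(
        "alpine",
        "forest",
        "forest",
        "forest",
        "forest",
        "shrubland",
        "shrubland",
        "shrubland",
        "agriculture_developed",
        "agriculture_developed",
        "agriculture_developed",
        "agriculture_developed",
        "other",
        "other",
        "other",
    ),
)

#: Category-level scheme used for aggregated (5-class) grids.
CATEGORY_SCHEME = ClassScheme(
    codes=tuple(range(1, len(CATEGORIES) + 1)),
    names=CATEGORIES,
    categories=CATEGORIES,
)

# Forest band class codes of DEFAULT_SCHEME keyed by lower band edge.
_FOREST_BAND_CODES = {0.0: 5, 600.0: 4, 1800.0: 3, 2500.0: 2}


def forest_class_for_elevation(elevation: np.ndarray) -> np.ndarray:
    """Forest-band class code for each elevation (vectorized, half-open bands)."""
    elevation = np.asarray(elevation, dtype=float)
    out = np.full(elevation.shape, _FOREST_BAND_CODES[0.0], dtype=np.int32)
    out[elevation >= 600.0] = _FOREST_BAND_CODES[600.0]
    out[elevation >= 1800.0] = _FOREST_BAND_CODES[1800.0]
    out[elevation >= 2500.0] = _FOREST_BAND_CODES[2500.0]
    return out


@dataclass
class LandCoverGrid:
    """Single-epoch categorical raster with class scheme and nodata code."""

    values: np.ndarray
    scheme: ClassScheme = DEFAULT_SCHEME
    nodata: int = 0
    transform: GridTransform = field(default_factory=GridTransform)
    epoch: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or 0 in self.values.shape:
            raise ValueError("grid must be a non-empty 2-D array")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("class grid must be integer-typed")
        if self.nodata in self.scheme.codes:
            raise ValueError("nodata code collides with a class code")
        self.validate_codes()

    def validate_codes(self) -> None:
        data = self.values[self.values != self.nodata]
        bad = np.unique(data[~self.scheme.contains(data)])
        if bad.size:
            raise ValueError(f"codes outside scheme: {bad.tolist()}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata

    @property
    def cell_area_ha(self) -> float:
        return self.transform.cell_area_ha

    def class_areas_ha(self) -> dict[int, float]:
        """Mapped area per class (ha) over valid cells."""
        codes, counts = np.unique(self.values[self.valid_mask], return_counts=True)
        area = self.cell_area_ha
        return {int(c): float(n) * area for c, n in zip(codes, counts)}

    def category_mask(self, category: str) -> np.ndarray:
        return np.isin(self.values, self.scheme.codes_for_category(category))

    def copy_with(self, values: np.ndarray) -> "LandCoverGrid":
        return LandCoverGrid(
            values=np.asarray(values),
            scheme=self.scheme,
            nodata=self.nodata,
            transform=self.transform,
            epoch=self.epoch,
        )


@dataclass
class CovariateStack:
    """Named, mutually aligned predictor layers.

    ``categorical`` lists layer names holding integer class labels (soil,
    landform, degradation); everything else is treated as continuous.
    """

    layers: dict[str, np.ndarray]
    transform: GridTransform = field(default_factory=GridTransform)
    categorical: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("empty covariate stack")
        shapes = {name: arr.shape for name, arr in self.layers.items()}
        first = next(iter(shapes.values()))
        for name, shp in shapes.items():
            if shp != first:
                raise ValueError(f"layer {name!r} shape {shp} != {first}")
        self.categorical = frozenset(self.categorical)
        unknown = self.categorical - set(self.layers)
        if unknown:
            raise ValueError(f"categorical names not in layers: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.layers.values())).shape

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.layers)

    def continuous_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.layers if n not in self.categorical)

    def table(self, rows: np.ndarray, cols: np.ndarray, names: Sequence[str] | None = None):
        """Extract a (n_cells, n_layers) matrix of layer values at cell indices."""
        names = tuple(names) if names is not None else self.names
        return np.column_stack([np.asarray(self.layers[n])[rows, cols] for n in names])

    def subset(self, names: Iterable[str]) -> "CovariateStack":
        names = tuple(names)
        return CovariateStack(
            layers={n: self.layers[n] for n in names},
            transform=self.transform,
            categorical=self.categorical & set(names),
        )


@dataclass(frozen=True)
class AlignmentCheck:
    """Truthiness-preserving result of an alignment check with a diagnostic."""

    ok: bool
    message: str = ""

    def __bool__(self) -> bool:
        return self.ok


def _shape_transform(obj) -> tuple[tuple[int, int], GridTransform]:
    if isinstance(obj, (LandCoverGrid, CovariateStack)):
        return obj.shape, obj.transform
    raise TypeError(f"cannot align object of type {type(obj).__name__}")


def assert_aligned(grids: Sequence) -> AlignmentCheck:
    """Check that all grids/stacks share dimensions and georeference.

    Returns a truthy :class:`AlignmentCheck`; on mismatch the message names
    the first offending pair.  Never raises for mismatches.
    """
    grids = list(grids)
    if len(grids) < 2:
        raise ValueError("need at least two grids to compare")
    shape0, tr0 = _shape_transform(grids[0])
    for i, g in enumerate(grids[1:], start=1):
        shape, tr = _shape_transform(g)
        if shape != shape0:
            return AlignmentCheck(False, f"grid 0 shape {shape0} != grid {i} shape {shape}")
        if not tr0.close_to(tr):
            return AlignmentCheck(False, f"grid 0 transform {tr0} != grid {i} transform {tr}")
    return AlignmentCheck(True)


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def _geo_extratags(transform: GridTransform, nodata) -> list:
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (float(transform.dx), float(transform.dy), 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(transform.x0), float(transform.y0), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata)),
    ]


def _read_geo_tags(page) -> tuple[GridTransform, str | None]:
    scale = page.tags.get(_TAG_PIXEL_SCALE)
    tie = page.tags.get(_TAG_TIEPOINT)
    nod = page.tags.get(_TAG_GDAL_NODATA)
    transform = GridTransform()
    if scale is not None and tie is not None:
        sx, sy = scale.value[0], scale.value[1]
        x0, y0 = tie.value[3], tie.value[4]
        transform = GridTransform(x0=float(x0), y0=float(y0), dx=float(sx), dy=float(sy))
    nodata = str(nod.value) if nod is not None else None
    return transform, nodata


def write_landcover(grid: LandCoverGrid, path) -> Path:
    """Write a class grid as a single-band int32 GeoTIFF."""
    path = Path(path)
    tifffile.imwrite(
        path,
        grid.values.astype(np.int32),
        extratags=_geo_extratags(grid.transform, grid.nodata),
    )
    return path


def read_landcover(path, scheme: ClassScheme = DEFAULT_SCHEME, epoch: str | None = None) -> LandCoverGrid:
    """Read a single-band integer GeoTIFF, validating codes against *scheme*."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        transform, nodata = _read_geo_tags(page)
    if values.ndim != 2:
        raise ValueError(f"{path}: expected a single-band raster")
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError(f"{path}: expected an integer band, got {values.dtype}")
    nodata_code = int(nodata) if nodata is not None else 0
    return LandCoverGrid(
        values=values, scheme=scheme, nodata=nodata_code, transform=transform, epoch=epoch
    )


def write_raster(values: np.ndarray, transform: GridTransform, path, nodata: float = np.nan) -> Path:
    """Write a float32 single-band GeoTIFF (covariates, densities)."""
    path = Path(path)
    tifffile.imwrite(
        path,
        np.asarray(values, dtype=np.float32),
        extratags=_geo_extratags(transform, nodata),
    )
    return path


def read_raster(path) -> tuple[np.ndarray, GridTransform]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        values = page.asarray()
        transform, _ = _read_geo_tags(page)
    return values, transform


# ---------------------------------------------------------------------------
# Pixel polygons (training / validation areas)


@dataclass
class PixelPolygon:
    """Connected block of same-class cells used as a training/validation area."""

    class_code: int
    cells: np.ndarray  # (n, 2) array of (row, col)
    role: str = "training"
    pid: int = 0

    def __post_init__(self) -> None:
        self.cells = np.atleast_2d(np.asarray(self.cells, dtype=np.int64))
        if self.cells.shape[1] != 2 or self.cells.shape[0] == 0:
            raise ValueError("cells must be a non-empty (n, 2) array")

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def geometry(self, transform: GridTransform):
        return unary_union([transform.cell_box(r, c) for r, c in self.cells])


def write_polygons(polygons: Sequence[PixelPolygon], transform: GridTransform, path) -> Path:
    """Write polygons as a GeoJSON FeatureCollection (cells kept as properties)."""
    features = []
    for p in polygons:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(p.geometry(transform)),
                "properties": {
                    "class_code": int(p.class_code),
                    "role": p.role,
                    "pid": int(p.pid),
                    "cells": [[int(r), int(c)] for r, c in p.cells],
                },
            }
        )
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path


def read_polygons(path) -> list[PixelPolygon]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        props = feat["properties"]
        out.append(
            PixelPolygon(
                class_code=int(props["class_code"]),
                cells=np.asarray(props["cells"], dtype=np.int64),
                role=props.get("role", "training"),
                pid=int(props.get("pid", 0)),
            )
        )
    return out
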