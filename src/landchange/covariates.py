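"""Predictor layers derived from a DEM and reflectance stacks.

Slope and aspect use Horn's 3x3 finite differences (the common GIS
convention) with edge replication; TPI uses a square neighbourhood with the
center cell excluded.  All derivatives are deterministic and invariant to
vertical translation of the DEM.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .grids import GridTransform

__all__ = [
    "horn_gradients",
    "slope",
    "northness",
    "tpi",
    "ndvi",
    "ndvi_change",
    "distance_to",
]


def _check_dem(dem: np.ndarray) -> np.ndarray:
    dem = np.asarray(dem, dtype=float)
    if dem.ndim != 2 or dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be 2-D and at least 3x3")
    if not np.isfinite(dem).any():
        raise ValueError("DEM contains no finite cells")
    return dem


def horn_gradients(dem: np.ndarray, cell_size: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """Horn 3x3 gradients (east, north components of the elevation surface).

    Returns ``(gx, gy)`` where ``gx`` is dz/dx toward the east and ``gy`` is
    dz/dy toward the north (row 0 is the northernmost row).  Borders use
    edge-replicated padding.
    """
    dem = _check_dem(dem)
    p = np.pad(dem, 1, mode="edge")
    # 3x3 window:  a b c
    #              d e f
    #              g h i
    a = p[:-2, :-2]
    b = p[:-2, 1:-1]
    c = p[:-2, 2:]
    d = p[1:-1, :-2]
    f = p[1:-1, 2:]
    g = p[2:, :-2]
    h = p[2:, 1:-1]
    i = p[2:, 2:]
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell_size)
    # rows increase southward, so north derivative flips sign
    gy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * cell_size)
    return gx, gy


def slope(dem: np.ndarray, cell_size: float = 30.0) -> np.ndarray:
    """Slope in degrees from Horn gradients."""
    gx, gy = horn_gradients(dem, cell_size)
    return np.degrees(np.arctan(np.hypot(gx, gy)))


def northness(dem: np.ndarray, cell_size: float = 30.0) -> np.ndarray:
    """Cosine of terrain aspect (+1 north-facing, -1 south-facing, flat -> 0).

    Aspect is the compass direction of the downhill vector; its cosine equals
    the north component of the unit downslope direction.
    """
    gx, gy = horn_gradients(dem, cell_size)
    mag = np.hypot(gx, gy)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(mag > 0, -gy / mag, 0.0)
    return out


def tpi(dem: np.ndarray, radius: int = 5) -> np.ndarray:
    """Topographic position index: elevation minus mean of the square
    neighbourhood of half-width *radius*, center excluded.

    Positive on ridges, negative in valleys.  Borders use edge replication.
    """
    dem = _check_dem(dem)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    if 2 * radius + 1 > max(dem.shape):
        raise ValueError("radius larger than grid")
    size = 2 * radius + 1
    n = size * size
    window_mean = ndimage.uniform_filter(dem, size=size, mode="nearest")
    neighbour_mean = (window_mean * n - dem) / (n - 1)
    return dem - neighbour_mean


def ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """(NIR - Red) / (NIR + Red); zero-sum cells become NaN."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    if red.shape != nir.shape:
        raise ValueError(f"misaligned bands: {red.shape} vs {nir.shape}")
    if (red < 0).any() or (nir < 0).any():
        raise ValueError("reflectance must be non-negative")
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, (nir - red) / denom, np.nan)
    return out


def ndvi_change(stack_t1: np.ndarray, stack_t2: np.ndarray) -> np.ndarray:
    """Per-cell median over period 1 minus median over period 2.

    Stacks are (n_dates, rows, cols) with NaN marking cloudy observations;
    cells with no clear observation in a period become NaN.  The sign
    convention is earlier minus later, so vegetation loss is positive.
    """
    stack_t1 = np.atleast_3d(np.asarray(stack_t1, dtype=float))
    stack_t2 = np.atleast_3d(np.asarray(stack_t2, dtype=float))
    if stack_t1.shape[0] == 0 or stack_t2.shape[0] == 0:
        raise ValueError("empty NDVI stack")
    if stack_t1.shape[1:] != stack_t2.shape[1:]:
        raise ValueError("NDVI stacks are misaligned")
    with np.errstate(invalid="ignore"), _suppress_all_nan():
        med1 = np.nanmedian(stack_t1, axis=0)
        med2 = np.nanmedian(stack_t2, axis=0)
    return med1 - med2


class _suppress_all_nan:
    """Silence numpy's all-NaN slice warning; NaN output is the contract."""

    def __enter__(self):
        import warnings

        self._cm = warnings.catch_warnings()
        self._cm.__enter__()
        import warnings as w

        w.filterwarnings("ignore", message="All-NaN slice encountered")
        return self

    def __exit__(self, *exc):
        return self._cm.__exit__(*exc)


def distance_to(features: np.ndarray, transform: GridTransform | None = None) -> np.ndarray:
    """Euclidean distance (m) from each cell center to the nearest feature cell."""
    features = np.asarray(features, dtype=bool)
    if not features.any():
        raise ValueError("no feature cells")
    if transform is None:
        transform = GridTransform()
    return ndimage.distance_transform_edt(
        ~features, sampling=(transform.dy, transform.dx)
    )
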