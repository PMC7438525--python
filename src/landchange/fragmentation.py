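"""Multiscale forest-area-density (FAD) fragmentation analysis.

FAD of a forest cell is the fraction of cells in the centered window x window
neighbourhood that are forest.  The implementation uses a summed-area table
and is bit-equal to naive counting.  Off-raster cells count as non-forest
with a constant window^2 denominator, so map edges are conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SCALES",
    "FAD_BINS",
    "FAD_CLASS_NAMES",
    "FADResult",
    "fad_map",
    "interior_mask",
    "classify_fad",
    "interior_change",
    "compute_fad",
    "fragmentation_summary",
]

#: Window sides (cells) evaluated by default; at 30 m cells these correspond
#: to neighbourhoods of 4.41, 15.21, 65.61, 590.49 and 5,314.41 ha.
DEFAULT_SCALES = (7, 13, 27, 81, 243)

INTERIOR_THRESHOLD = 0.9

#: Density bins: rare, patchy, transitional, dominant, interior.
FAD_BINS = (0.0, 0.1, 0.4, 0.6, 0.9)
FAD_CLASS_NAMES = ("rare", "patchy", "transitional", "dominant", "interior")


@dataclass
class FADResult:
    """Per-scale density and fragmentation classification of forest cells."""

    window: int
    density: np.ndarray  # NaN off forest
    class_grid: np.ndarray  # 0 off forest, 1..5 on forest cells
    interior: np.ndarray  # boolean
    unreliable: np.ndarray  # window > 50% nodata
    cell_area_ha: float = 0.09

    @property
    def scale_ha(self) -> float:
        return self.window * self.window * self.cell_area_ha

    @property
    def interior_area_ha(self) -> float:
        return float(self.interior.sum()) * self.cell_area_ha

    @property
    def forest_area_ha(self) -> float:
        return float(np.isfinite(self.density).sum()) * self.cell_area_ha

    def class_proportions(self) -> np.ndarray:
        """Fraction of forest cells per fragmentation class (sums to 1)."""
        forest = np.isfinite(self.density)
        n = forest.sum()
        if n == 0:
            return np.zeros(len(FAD_CLASS_NAMES))
        return np.array(
            [(self.class_grid[forest] == k).sum() / n for k in range(1, len(FAD_CLASS_NAMES) + 1)]
        )


def _window_counts(mask: np.ndarray, window: int) -> np.ndarray:
    """Count of True cells in the centered window, via a summed-area table.

    Off-raster cells contribute zero; integer arithmetic keeps the result
    bit-equal to naive counting.
    """
    half = window // 2
    padded = np.zeros((mask.shape[0] + 2 * half + 1, mask.shape[1] + 2 * half + 1), dtype=np.int64)
    padded[half + 1 : half + 1 + mask.shape[0], half + 1 : half + 1 + mask.shape[1]] = mask
    sat = padded.cumsum(axis=0).cumsum(axis=1)
    r0 = np.arange(mask.shape[0])
    c0 = np.arange(mask.shape[1])
    top = r0[:, None]
    bottom = r0[:, None] + window
    left = c0[None, :]
    right = c0[None, :] + window
    return sat[bottom, right] - sat[top, right] - sat[bottom, left] + sat[top, left]


def fad_map(forest_mask: np.ndarray, window: int) -> np.ndarray:
    """Forest-area density at one scale; NaN on non-forest cells.

    The denominator is the constant window^2, so densities near the raster
    edge are depressed rather than inflated.
    """
    forest_mask = np.asarray(forest_mask, dtype=bool)
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > max(forest_mask.shape):
        raise ValueError("window larger than both grid dimensions")
    counts = _window_counts(forest_mask, window)
    density = counts / float(window * window)
    density[~forest_mask] = np.nan
    return density


def interior_mask(density: np.ndarray, threshold: float = INTERIOR_THRESHOLD) -> np.ndarray:
    """Forest-interior cells: density >= threshold (inclusive)."""
    with np.errstate(invalid="ignore"):
        return np.asarray(density >= threshold)


def classify_fad(density: np.ndarray) -> np.ndarray:
    """Bin densities into the 5 fragmentation classes (1..5); 0 off forest."""
    out = np.zeros(density.shape, dtype=np.int8)
    forest = np.isfinite(density)
    d = density[forest]
    cls = np.digitize(d, FAD_BINS[1:], right=False) + 1
    out[forest] = cls
    return out


def interior_change(epoch1_interior: float, epoch2_interior: float) -> tuple[float, float]:
    """(absolute change, percent change relative to epoch 1)."""
    if epoch1_interior < 0 or epoch2_interior < 0:
        raise ValueError("areas must be non-negative")
    delta = epoch2_interior - epoch1_interior
    if epoch1_interior == 0:
        if epoch2_interior == 0:
            return 0.0, 0.0
        raise ValueError("percent change undefined: epoch-1 interior area is zero")
    return delta, 100.0 * delta / epoch1_interior


def compute_fad(
    forest_mask: np.ndarray,
    window: int,
    nodata_mask: np.ndarray | None = None,
    cell_area_ha: float = 0.09,
) -> FADResult:
    """Full per-scale result: density, classes, interior and reliability.

    Nodata cells count as non-forest in the numerator; cells whose window is
    more than half nodata are flagged unreliable.
    """
    density = fad_map(forest_mask, window)
    if nodata_mask is not None:
        nodata_counts = _window_counts(np.asarray(nodata_mask, dtype=bool), window)
        unreliable = nodata_counts > (window * window) / 2.0
    else:
        unreliable = np.zeros(forest_mask.shape, dtype=bool)
    return FADResult(
        window=window,
        density=density,
        class_grid=classify_fad(density),
        interior=interior_mask(density),
        unreliable=unreliable,
        cell_area_ha=cell_area_ha,
    )


def fragmentation_summary(
    epoch1_results: dict[int, FADResult], epoch2_results: dict[int, FADResult]
) -> pd.DataFrame:
    """Per-scale interior areas, change, and fragmentation-class proportions."""
    if set(epoch1_results) != set(epoch2_results):
        raise ValueError("scale mismatch between epochs")
    rows = []
    for window in sorted(epoch1_results):
        r1, r2 = epoch1_results[window], epoch2_results[window]
        a1, a2 = r1.interior_area_ha, r2.interior_area_ha
        try:
            delta, pct = interior_change(a1, a2)
        except ValueError:
            delta, pct = a2 - a1, np.nan
        row = {
            "window_cells": window,
            "scale_ha": r1.scale_ha,
            "interior_epoch1_ha": a1,
            "interior_epoch2_ha": a2,
            "change_ha": delta,
            "change_pct": pct,
        }
        for name, p1, p2 in zip(FAD_CLASS_NAMES, r1.class_proportions(), r2.class_proportions()):
            row[f"prop_{name}_epoch1"] = p1
            row[f"prop_{name}_epoch2"] = p2
        rows.append(row)
    return pd.DataFrame(rows)
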