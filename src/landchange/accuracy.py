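"""Error-matrix accuracy metrics and error-adjusted area estimation.

Implements the stratified estimator for map accuracy and class areas from a
reference sample: cell proportions are weighted by mapped-area shares, and
the 95% confidence interval of each adjusted area uses the standard
per-stratum binomial variance with a normal z of 1.96.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import LandCoverGrid, PixelPolygon

__all__ = [
    "ErrorMatrix",
    "AccuracyReport",
    "sample_validation_pixels",
    "build_error_matrix",
    "olofsson_estimates",
]

Z_95 = 1.96


@dataclass
class ErrorMatrix:
    """Reference-vs-mapped counts with mapped-area weights.

    ``counts[i, j]`` is the number of reference cells mapped as class
    ``labels[i]`` whose reference label is ``labels[j]``.
    """

    labels: tuple[int, ...]
    counts: np.ndarray
    mapped_area_ha: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.mapped_area_ha = np.asarray(self.mapped_area_ha, dtype=float)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over labels")
        if (self.counts < 0).any() or (self.mapped_area_ha < 0).any():
            raise ValueError("counts and areas must be non-negative")

    @property
    def total_area_ha(self) -> float:
        return float(self.mapped_area_ha.sum())

    @property
    def weights(self) -> np.ndarray:
        return self.mapped_area_ha / self.total_area_ha

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass
class AccuracyReport:
    labels: tuple[int, ...]
    overall_accuracy: float
    users_accuracy: np.ndarray
    producers_accuracy: np.ndarray
    adjusted_area_ha: np.ndarray
    area_ci_ha: np.ndarray  # 95% half-widths
    total_area_ha: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class": list(self.labels),
                "users_accuracy": self.users_accuracy,
                "producers_accuracy": self.producers_accuracy,
                "adjusted_area_ha": self.adjusted_area_ha,
                "area_ci95_ha": self.area_ci_ha,
            }
        )


def sample_validation_pixels(
    polygons: list[PixelPolygon], per_polygon: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference sample: up to *per_polygon* cells per validation polygon.

    Returns (rows, cols, reference labels).
    """
    if not polygons:
        raise ValueError("empty validation polygon set")
    rng = np.random.default_rng(seed)
    rows, cols, labels = [], [], []
    for p in polygons:
        k = min(per_polygon, p.n_cells)
        take = rng.choice(p.n_cells, size=k, replace=False)
        rows.append(p.cells[take, 0])
        cols.append(p.cells[take, 1])
        labels.append(np.full(k, p.class_code, dtype=np.int32))
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(labels)


def build_error_matrix(
    landcover: LandCoverGrid,
    rows: np.ndarray,
    cols: np.ndarray,
    reference_labels: np.ndarray,
) -> ErrorMatrix:
    """Cross-tabulate mapped vs reference labels at the sample cells."""
    reference_labels = np.asarray(reference_labels)
    bad = set(np.unique(reference_labels)) - set(landcover.scheme.codes)
    if bad:
        raise ValueError(f"reference labels outside scheme: {sorted(bad)}")
    labels = tuple(landcover.scheme.codes)
    index = {c: i for i, c in enumerate(labels)}
    mapped = landcover.values[np.asarray(rows), np.asarray(cols)]
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    for m, r in zip(mapped, reference_labels):
        if m == landcover.nodata:
            continue  # reference cell fell on a map gap; not attributable
        counts[index[int(m)], index[int(r)]] += 1
    areas = landcover.class_areas_ha()
    mapped_area = np.array([areas.get(c, 0.0) for c in labels])
    return ErrorMatrix(labels=labels, counts=counts, mapped_area_ha=mapped_area)


def olofsson_estimates(em: ErrorMatrix) -> AccuracyReport:
    """Error-adjusted accuracies and areas with 95% CIs.

    Classes absent from the map (zero mapped area) are excluded from the
    estimation with a warning.  Any mapped class whose reference-sample row
    has fewer than 2 cells makes the variance undefined and raises.
    """
    keep = em.mapped_area_ha > 0
    if not keep.all():
        dropped = [l for l, k in zip(em.labels, keep) if not k]
        warnings.warn(f"classes absent from map excluded: {dropped}", stacklevel=2)
    labels = tuple(l for l, k in zip(em.labels, keep) if k)
    counts = em.counts[np.ix_(keep, keep)]
    areas = em.mapped_area_ha[keep]
    total = float(areas.sum())
    weights = areas / total

    row_totals = counts.sum(axis=1)
    if (row_totals <= 1).any():
        bad = [l for l, n in zip(labels, row_totals) if n <= 1]
        raise ValueError(f"classes with <2 reference cells in their map stratum: {bad}")

    # area-weighted cell proportions
    p = weights[:, None] * counts / row_totals[:, None]
    overall = float(np.trace(p))
    users = np.diag(p) / p.sum(axis=1)
    col_p = p.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        producers = np.where(col_p > 0, np.diag(p) / col_p, np.nan)
    adjusted = total * col_p

    frac = counts / row_totals[:, None]
    var_terms = weights[:, None] ** 2 * frac * (1.0 - frac) / (row_totals[:, None] - 1)
    se = total * np.sqrt(var_terms.sum(axis=0))
    return AccuracyReport(
        labels=labels,
        overall_accuracy=overall,
        users_accuracy=users,
        producers_accuracy=producers,
        adjusted_area_ha=adjusted,
        area_ci_ha=Z_95 * se,
        total_area_ha=total,
    )
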