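"""Category aggregation, transition accounting, change rates and Sankey export."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import CATEGORY_SCHEME, LandCoverGrid, assert_aligned

__all__ = [
    "TransitionMatrix",
    "aggregate_to_categories",
    "transition_matrix",
    "annual_rate",
    "gross_loss_fraction",
    "gain_loss_map",
    "sankey_export",
    "GAIN_LOSS_CODES",
]

#: Change-map codes for :func:`gain_loss_map`.
GAIN_LOSS_CODES = {"stable_focus": 1, "gain": 2, "loss": 3, "stable_other": 4, "nodata": 0}


@dataclass
class TransitionMatrix:
    """Pixel-by-pixel from/to cross-tabulation over commonly valid cells."""

    labels: tuple[int, ...]
    counts: np.ndarray
    cell_area_ha: float
    epochs: tuple[str | None, str | None] = (None, None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over labels")

    @property
    def valid_cell_count(self) -> int:
        return int(self.counts.sum())

    @property
    def areas_ha(self) -> np.ndarray:
        return self.counts * self.cell_area_ha

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))

    def aggregate(self, code_map: dict[int, int]) -> "TransitionMatrix":
        """Sum flows into coarser labels via *code_map* (old code -> new code)."""
        new_labels = tuple(sorted(set(code_map.values())))
        index = {c: i for i, c in enumerate(new_labels)}
        k = len(new_labels)
        out = np.zeros((k, k), dtype=np.int64)
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                out[index[code_map[a]], index[code_map[b]]] += self.counts[i, j]
        return TransitionMatrix(
            labels=new_labels, counts=out, cell_area_ha=self.cell_area_ha, epochs=self.epochs
        )


def aggregate_to_categories(grid: LandCoverGrid) -> LandCoverGrid:
    """Recode a class grid to the 5 vegetation categories; nodata preserved."""
    cat_code = {c: CATEGORY_SCHEME.codes[CATEGORY_SCHEME.names.index(cat)]
                for c, cat in grid.scheme.category_map.items()}
    lut = np.zeros(max(grid.scheme.codes) + 1, dtype=np.int32)
    for code, new in cat_code.items():
        lut[code] = new
    values = np.where(grid.valid_mask, lut[grid.values], 0).astype(np.int32)
    return LandCoverGrid(
        values=values,
        scheme=CATEGORY_SCHEME,
        nodata=0,
        transform=grid.transform,
        epoch=grid.epoch,
    )


def category_code(category: str) -> int:
    return CATEGORY_SCHEME.codes[CATEGORY_SCHEME.names.index(category)]


def transition_matrix(epoch1: LandCoverGrid, epoch2: LandCoverGrid) -> TransitionMatrix:
    """From/to cell counts between epochs over cells valid in both."""
    check = assert_aligned([epoch1, epoch2])
    if not check:
        raise ValueError(f"misaligned epochs: {check.message}")
    if epoch1.scheme.codes != epoch2.scheme.codes:
        raise ValueError("epochs use different class schemes")
    labels = tuple(epoch1.scheme.codes)
    index = np.zeros(max(labels) + 1, dtype=np.int64)
    for i, c in enumerate(labels):
        index[c] = i
    valid = epoch1.valid_mask & epoch2.valid_mask
    a = index[epoch1.values[valid]]
    b = index[epoch2.values[valid]]
    k = len(labels)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    return TransitionMatrix(
        labels=labels,
        counts=counts,
        cell_area_ha=epoch1.cell_area_ha,
        epochs=(epoch1.epoch, epoch2.epoch),
    )


def annual_rate(area_t1: float, area_t2: float, years: float) -> float:
    """Annual compound rate of area change in %/yr (positive = loss).

    r = (100 / years) * ln(area_t1 / area_t2)
    """
    if area_t1 <= 0 or area_t2 <= 0:
        raise ValueError("areas must be positive")
    if years <= 0:
        raise ValueError("interval must be positive")
    return (100.0 / years) * float(np.log(area_t1 / area_t2))


def gross_loss_fraction(tm: TransitionMatrix, focus_codes, sink_codes) -> float:
    """EXPERIMENTAL: gross flow from focus classes into sink classes as a
    fraction of the epoch-1 focus area.  One candidate reading of a
    study-period loss percentage; its exact definition is not settled."""
    idx = {c: i for i, c in enumerate(tm.labels)}
    f = [idx[c] for c in focus_codes]
    s = [idx[c] for c in sink_codes]
    source_total = tm.counts[f, :].sum()
    if source_total == 0:
        raise ValueError("no focus cells in epoch 1")
    return float(tm.counts[np.ix_(f, s)].sum() / source_total)


def gain_loss_map(
    epoch1: LandCoverGrid, epoch2: LandCoverGrid, focus: str = "forest"
) -> LandCoverGrid:
    """Per-cell change codes for a focus category (stable/gain/loss)."""
    check = assert_aligned([epoch1, epoch2])
    if not check:
        raise ValueError(f"misaligned epochs: {check.message}")
    f1 = epoch1.category_mask(focus)
    f2 = epoch2.category_mask(focus)
    valid = epoch1.valid_mask & epoch2.valid_mask
    out = np.full(epoch1.shape, GAIN_LOSS_CODES["nodata"], dtype=np.int32)
    out[valid & f1 & f2] = GAIN_LOSS_CODES["stable_focus"]
    out[valid & ~f1 & f2] = GAIN_LOSS_CODES["gain"]
    out[valid & f1 & ~f2] = GAIN_LOSS_CODES["loss"]
    out[valid & ~f1 & ~f2] = GAIN_LOSS_CODES["stable_other"]
    scheme = _gain_loss_scheme()
    return LandCoverGrid(values=out, scheme=scheme, nodata=0, transform=epoch1.transform)


def _gain_loss_scheme():
    from .grids import ClassScheme

    return ClassScheme(
        codes=(1, 2, 3, 4),
        names=("stable_focus", "gain", "loss", "stable_other"),
        categories=("other", "other", "other", "other"),
    )


def sankey_export(tm: TransitionMatrix, names: dict[int, str] | None = None) -> list[dict]:
    """Nonzero flows as (source, target, value_ha) records."""
    names = names or {c: str(c) for c in tm.labels}
    records = []
    areas = tm.areas_ha
    for i, a in enumerate(tm.labels):
        for j, b in enumerate(tm.labels):
            if tm.counts[i, j] > 0:
                records.append(
                    {
                        "source": names[a],
                        "target": names[b],
                        "value_ha": float(areas[i, j]),
                    }
                )
    return records


def write_sankey_json(records: list[dict], path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(records, indent=2))
    return path
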