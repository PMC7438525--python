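"""Synthetic paired-epoch landscapes with known ground truth.

Generates elevation-banded land cover, covariate stacks, cloud masks,
training/validation pixel polygons, and an epoch-2 map drawn from a known
three-outcome multinomial logit per source category.  Everything is
deterministic given the scenario seed, so generator scenes double as
parameter-recovery oracles for the downstream estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import covariates as cov
from .grids import (
    CATEGORIES,
    DEFAULT_SCHEME,
    ClassScheme,
    CovariateStack,
    GridTransform,
    LandCoverGrid,
    PixelPolygon,
    forest_class_for_elevation,
)

__all__ = [
    "ScenarioConfig",
    "SyntheticScene",
    "DEFAULT_TRUTH",
    "generate_elevation",
    "generate_scene_pair",
    "sample_polygons",
    "apply_cloud_mask",
    "perturb_classification",
]

# Alternative (non-stay) outcome categories per modelled source category.
ALT_OUTCOMES: dict[str, tuple[str, str]] = {
    "forest": ("shrubland", "agriculture_developed"),
    "shrubland": ("forest", "agriculture_developed"),
    "agriculture_developed": ("forest", "shrubland"),
}

#: Ground-truth multinomial coefficients over standardized covariates.
#: Keys: source category -> alternative outcome -> {covariate or 'intercept': beta}.
DEFAULT_TRUTH: dict[str, dict[str, dict[str, float]]] = {
    "forest": {
        "shrubland": {"intercept": -2.4, "temperature": 0.8, "dist_village": -0.6},
        "agriculture_developed": {"intercept": -3.2, "temperature": 0.7, "dist_village": -1.0},
    },
    "shrubland": {
        "forest": {"intercept": -1.0, "dist_village": 0.5},
        "agriculture_developed": {"intercept": -1.6, "dist_village": -0.8},
    },
    "agriculture_developed": {
        "forest": {"intercept": -1.6, "temperature": -0.6},
        "shrubland": {"intercept": -1.3, "slope": 0.4},
    },
}


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic scenario; seed pins every random draw."""

    shape: tuple[int, int] = (150, 150)
    seed: int = 0
    elevation_range: tuple[float, float] = (420.0, 5882.0)
    band_edges: tuple[float, ...] = (600.0, 1800.0, 2500.0, 3000.0)
    n_villages: int = 3
    degradation_intensity: float = 0.5
    transition_coefficients: dict = field(default_factory=lambda: _copy_truth(DEFAULT_TRUTH))
    cloud_fraction: float = 0.17
    noise_scale: float = 12.0
    snow_elevation: float = 5000.0
    impact_radius_cells: float = 12.0
    training_polygons_per_class: int = 8
    validation_polygons_per_class: int = 4
    max_polygon_extent: int = 6

    def __post_init__(self) -> None:
        if not (0.0 <= self.cloud_fraction < 1.0):
            raise ValueError("cloud_fraction must be in [0, 1)")
        if any(b >= a for a, b in zip(self.band_edges[1:], self.band_edges[:-1])):
            raise ValueError("band edges must be strictly increasing")
        if self.elevation_range[0] >= self.elevation_range[1]:
            raise ValueError("elevation range must be increasing")
        if self.n_villages == 0 and self.degradation_intensity > 0:
            raise ValueError("degradation without villages is degenerate")


def _copy_truth(truth):
    return {s: {o: dict(b) for o, b in outs.items()} for s, outs in truth.items()}


@dataclass
class SyntheticScene:
    """A generated scene pair plus everything needed to audit it."""

    epoch1: LandCoverGrid
    epoch2: LandCoverGrid
    covariates: CovariateStack
    cloud_mask: np.ndarray
    truth: dict
    polygons: dict[str, list[PixelPolygon]] = field(default_factory=dict)

    @property
    def config(self) -> ScenarioConfig:
        return self.truth["config"]


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Spatially autocorrelated field, normalized to [0, 1]."""
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=sigma, mode="reflect")
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:  # pathological: constant field
        return np.zeros(shape)
    return (smooth - lo) / (hi - lo)


def generate_elevation(config: ScenarioConfig) -> np.ndarray:
    """Smooth autocorrelated elevation surface spanning exactly the
    configured range (min/max attained)."""
    rng = np.random.default_rng(config.seed)
    base = _smooth_field(rng, config.shape, config.noise_scale)
    lo, hi = config.elevation_range
    return lo + base * (hi - lo)


def _temperature(elevation: np.ndarray) -> np.ndarray:
    # 6.5 K/km lapse rate off a 25 degC valley-floor reference; kept noise-free
    # so temperature is strictly decreasing in elevation.
    return 25.0 - 6.5 * elevation / 1000.0


def _precipitation(elevation: np.ndarray, rng: np.random.Generator, sigma: float) -> np.ndarray:
    # orographic trend plus an independent weather field; the noise term is
    # sized so precipitation is not a pure function of elevation
    lo, hi = float(elevation.min()), float(elevation.max())
    frac = (elevation - lo) / max(hi - lo, 1.0)
    noise = _smooth_field(rng, elevation.shape, sigma)
    return 4000.0 + 2000.0 * frac + 1000.0 * (noise - 0.5)


def _base_classes(elevation: np.ndarray, slope_deg: np.ndarray, config: ScenarioConfig) -> np.ndarray:
    """Epoch-1 natural cover from elevation bands."""
    values = forest_class_for_elevation(elevation)
    alpine_edge = config.band_edges[-1]
    values[elevation >= alpine_edge] = 1  # alpine vegetation
    values[elevation >= config.snow_elevation] = 14  # snow/glacier
    rock = (slope_deg > 45.0) & (elevation >= alpine_edge) & (elevation < config.snow_elevation)
    values[rock] = 13
    return values.astype(np.int32)


def _river_mask(elevation: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A meandering column path marked as streambed where terrain is low."""
    rows, cols = elevation.shape
    mask = np.zeros(elevation.shape, dtype=bool)
    c = rng.integers(cols // 4, 3 * cols // 4)
    for r in range(rows):
        c = int(np.clip(c + rng.integers(-1, 2), 0, cols - 1))
        if elevation[r, c] < 1800.0:
            mask[r, c] = True
    return mask


def _place_villages(elevation: np.ndarray, config: ScenarioConfig, rng: np.random.Generator):
    flat_idx = np.argsort(elevation, axis=None)
    n_low = max(config.n_villages * 20, int(elevation.size * 0.1))
    candidates = flat_idx[:n_low]
    chosen = rng.choice(candidates, size=min(config.n_villages, candidates.size), replace=False)
    rows, cols = np.unravel_index(chosen, elevation.shape)
    return rows, cols


def _human_impact(
    values: np.ndarray,
    elevation: np.ndarray,
    dist_village: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
    cell_size: float,
) -> np.ndarray:
    """Seed agriculture/developed and degraded classes around villages."""
    out = values.copy()
    scale_m = config.impact_radius_cells * cell_size
    p = config.degradation_intensity * np.exp(-dist_village / max(scale_m, 1.0))
    impacted = (rng.random(values.shape) < p) & (elevation < 1800.0) & (values != 15)
    draw = rng.random(values.shape)
    low = elevation < 600.0
    # graded severity: closest cells become fields/clearcuts, fringe degrades
    out[impacted & (draw < 0.30) & low] = 10  # paddyfield
    out[impacted & (draw < 0.30) & ~low] = 9  # grassland/pasture
    out[impacted & (draw >= 0.30) & (draw < 0.55)] = 11  # clearcut
    sec = impacted & (draw >= 0.55) & (draw < 0.85)
    out[sec & low] = 7  # secondary forest < 600 m
    out[sec & ~low] = 6  # secondary forest 600-1,800 m
    out[impacted & (draw >= 0.85)] = 8  # shrub/bush
    return out


def _road_mask(shape, towns_rc, rng: np.random.Generator) -> np.ndarray:
    """Roads run from each town southward to the grid edge with jitter."""
    mask = np.zeros(shape, dtype=bool)
    rows, cols = shape
    for r0, c0 in towns_rc:
        c = int(c0)
        for r in range(int(r0), rows):
            c = int(np.clip(c + rng.integers(-1, 2), 0, cols - 1))
            mask[r, c] = True
    return mask


def _categorical_field(rng: np.random.Generator, shape, n_classes: int, sigma: float) -> np.ndarray:
    fields = np.stack([
        ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma) for _ in range(n_classes)
    ])
    return np.argmax(fields, axis=0).astype(np.int32) + 1


def _standardize_over(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    sel = values[mask]
    sd = sel.std()
    return (values - sel.mean()) / (sd if sd > 0 else 1.0)


def _draw_transitions(
    epoch1: np.ndarray,
    scheme: ClassScheme,
    stack: CovariateStack,
    elevation: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Epoch-2 classes: stay is the baseline outcome; movement follows the
    truth multinomial logit evaluated on z-scored covariates of the source
    cells."""
    epoch2 = epoch1.copy()
    cat_map = scheme.category_map
    for source, outcomes in config.transition_coefficients.items():
        source_codes = scheme.codes_for_category(source)
        mask = np.isin(epoch1, source_codes)
        n = int(mask.sum())
        if n == 0:
            continue
        alt_names = ALT_OUTCOMES[source]
        etas = np.zeros((n, len(alt_names)))
        for k, alt in enumerate(alt_names):
            beta = outcomes.get(alt, {})
            eta = np.full(n, float(beta.get("intercept", -np.inf)))
            for name, b in beta.items():
                if name == "intercept":
                    continue
                z = _standardize_over(np.asarray(stack.layers[name], dtype=float), mask)
                eta = eta + b * z[mask]
            etas[:, k] = eta
        expd = np.exp(etas)
        denom = 1.0 + expd.sum(axis=1)
        p_alt = expd / denom[:, None]
        u = rng.random(n)
        outcome = np.zeros(n, dtype=np.int64)  # 0 = stay
        cum = np.cumsum(p_alt, axis=1)
        for k in range(len(alt_names) - 1, -1, -1):
            outcome[u < cum[:, k]] = k + 1
        rows, cols = np.nonzero(mask)
        elev_cells = elevation[mask]
        new_vals = epoch1[mask].copy()
        for k, alt in enumerate(alt_names, start=1):
            sel = outcome == k
            if not sel.any():
                continue
            new_vals[sel] = _class_for_category(alt, elev_cells[sel], rng)
        epoch2[rows, cols] = new_vals
    return epoch2


def _class_for_category(category: str, elevation: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Concrete class code for cells entering *category*, respecting
    elevation bands where the scheme distinguishes them."""
    n = elevation.shape[0]
    if category == "forest":
        return forest_class_for_elevation(elevation)
    if category == "shrubland":
        out = np.full(n, 8, dtype=np.int32)  # shrub/bush above 1,800 m
        out[elevation < 1800.0] = 6
        out[elevation < 600.0] = 7
        return out
    if category == "agriculture_developed":
        draw = rng.random(n)
        out = np.full(n, 11, dtype=np.int32)  # clearcut
        out[draw < 0.3] = 9  # grassland/pasture
        return out
    raise ValueError(f"no transition class rule for category {category!r}")


def _cloud_blobs(shape, fraction: float, rng: np.random.Generator, sigma: float) -> np.ndarray:
    if fraction <= 0:
        return np.zeros(shape, dtype=bool)
    f = _smooth_field(rng, shape, sigma)
    threshold = np.quantile(f, 1.0 - fraction)
    return f >= threshold


def generate_scene_pair(config: ScenarioConfig, scheme: ClassScheme = DEFAULT_SCHEME) -> SyntheticScene:
    """Generate a complete two-epoch scene with covariates and ground truth."""
    rng = np.random.default_rng(config.seed)
    transform = GridTransform()
    elevation = generate_elevation(config)
    slope_deg = cov.slope(elevation, transform.dx)

    values = _base_classes(elevation, slope_deg, config)
    river = _river_mask(elevation, rng)
    values[river] = 15

    vr, vc = _place_villages(elevation, config, rng)
    village_mask = np.zeros(config.shape, dtype=bool)
    village_mask[vr, vc] = True
    n_towns = max(1, len(vr) // 3)
    town_mask = np.zeros(config.shape, dtype=bool)
    town_mask[vr[:n_towns], vc[:n_towns]] = True
    road = _road_mask(config.shape, list(zip(vr[:n_towns], vc[:n_towns])), rng)

    dist_village = cov.distance_to(village_mask, transform)
    values = _human_impact(values, elevation, dist_village, config, rng, transform.dx)
    values[vr, vc] = 12  # settlement cores

    stack = CovariateStack(
        layers={
            "elevation": elevation,
            "slope": slope_deg,
            "northness": cov.northness(elevation, transform.dx),
            "tpi": cov.tpi(elevation, radius=min(5, min(config.shape) // 2 - 1)),
            "temperature": _temperature(elevation),
            "precipitation": _precipitation(elevation, rng, config.noise_scale),
            "dist_village": dist_village,
            "dist_town": cov.distance_to(town_mask, transform),
            "dist_road": cov.distance_to(road, transform),
            "dist_river": cov.distance_to(river, transform) if river.any() else np.zeros(config.shape),
            "soil": _categorical_field(rng, config.shape, 3, config.noise_scale),
            "landform": _categorical_field(rng, config.shape, 3, config.noise_scale),
            "degradation": _categorical_field(rng, config.shape, 2, config.noise_scale),
        },
        transform=transform,
        categorical=frozenset({"soil", "landform", "degradation"}),
    )

    epoch2_values = _draw_transitions(values, scheme, stack, elevation, config, rng)

    # NDVI change (earlier minus later): positive where woody cover was lost.
    forest1 = np.isin(values, scheme.codes_for_category("forest"))
    forest2 = np.isin(epoch2_values, scheme.codes_for_category("forest"))
    cleared = forest1 & ~forest2
    ndvi_change = 0.05 * ndimage.gaussian_filter(
        rng.standard_normal(config.shape), sigma=config.noise_scale
    )
    ndvi_change[cleared] += 0.6
    stack.layers["ndvi_change"] = ndvi_change

    cloud_mask = _cloud_blobs(config.shape, config.cloud_fraction, rng, config.noise_scale / 2)

    epoch1 = LandCoverGrid(values, scheme=scheme, transform=transform, epoch="t1")
    epoch2 = LandCoverGrid(epoch2_values, scheme=scheme, transform=transform, epoch="t2")

    truth = {
        "config": config,
        "transition_counts": _category_transition_counts(epoch1, epoch2),
        "category_labels": list(CATEGORIES),
    }
    scene = SyntheticScene(
        epoch1=epoch1,
        epoch2=epoch2,
        covariates=stack,
        cloud_mask=cloud_mask,
        truth=truth,
    )
    training = sample_polygons(
        scene, per_class=config.training_polygons_per_class, role="training",
        seed=config.seed + 1,
    )
    validation = sample_polygons(
        scene, per_class=config.validation_polygons_per_class, role="validation",
        seed=config.seed + 2, exclude=training,
    )
    scene.polygons = {"training": training, "validation": validation}
    return scene


def _category_transition_counts(epoch1: LandCoverGrid, epoch2: LandCoverGrid) -> np.ndarray:
    cat_index = {c: i for i, c in enumerate(CATEGORIES)}
    k = len(CATEGORIES)
    counts = np.zeros((k, k), dtype=np.int64)
    cmap = epoch1.scheme.category_map
    code_to_idx = np.zeros(max(epoch1.scheme.codes) + 1, dtype=np.int64)
    for code, cat in cmap.items():
        code_to_idx[code] = cat_index[cat]
    a = code_to_idx[epoch1.values]
    b = code_to_idx[epoch2.values]
    np.add.at(counts, (a.ravel(), b.ravel()), 1)
    return counts


def sample_polygons(
    scene: SyntheticScene,
    per_class: int,
    role: str = "training",
    seed: int = 0,
    exclude: Sequence[PixelPolygon] = (),
    max_extent: int | None = None,
) -> list[PixelPolygon]:
    """Sample connected same-class rectangular cell blocks per class.

    Blocks are grown greedily from random seed cells up to
    ``max_extent x max_extent`` cells and never overlap cells used by
    *exclude* polygons, so training and validation sets stay disjoint.
    Classes with fewer blocks than requested yield a partial set with a
    warning.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    rng = np.random.default_rng(seed)
    grid = scene.epoch1
    max_extent = max_extent or scene.config.max_polygon_extent
    used = np.zeros(grid.shape, dtype=bool)
    for p in exclude:
        used[p.cells[:, 0], p.cells[:, 1]] = True

    polygons: list[PixelPolygon] = []
    pid = 0
    for code in grid.scheme.codes:
        available = (grid.values == code) & ~used
        got = 0
        attempts = 0
        idx = np.flatnonzero(available)
        rng.shuffle(idx)
        for flat in idx:
            if got >= per_class:
                break
            r, c = np.unravel_index(flat, grid.shape)
            if not available[r, c]:
                continue
            cells = _grow_block(available, int(r), int(c), max_extent)
            if cells is None:
                continue
            available[cells[:, 0], cells[:, 1]] = False
            used[cells[:, 0], cells[:, 1]] = True
            polygons.append(PixelPolygon(class_code=int(code), cells=cells, role=role, pid=pid))
            pid += 1
            got += 1
            attempts += 1
        if 0 < got < per_class or (got == 0 and (grid.values == code).any()):
            warnings.warn(
                f"class {code}: only {got}/{per_class} {role} polygons available",
                stacklevel=2,
            )
    return polygons


def _grow_block(available: np.ndarray, r: int, c: int, max_extent: int) -> np.ndarray | None:
    """Largest all-available rectangle anchored at (r, c), up to max_extent."""
    rows, cols = available.shape
    h = w = 1
    while h < max_extent and r + h < rows and available[r + h, c : c + w].all():
        h += 1
    while w < max_extent and c + w < cols and available[r : r + h, c : c + w + 1][:, -1].all():
        w += 1
    rr, cc = np.meshgrid(np.arange(r, r + h), np.arange(c, c + w), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()])


def apply_cloud_mask(grid: LandCoverGrid, cloud_mask: np.ndarray) -> LandCoverGrid:
    """Set cloudy cells to nodata (simulates gaps in an optical classification)."""
    values = grid.values.copy()
    values[np.asarray(cloud_mask, dtype=bool)] = grid.nodata
    return grid.copy_with(values)


def perturb_classification(
    grid: LandCoverGrid, error_rate: float, seed: int = 0
) -> LandCoverGrid:
    """Random label noise: each valid cell flips to a random other class with
    probability *error_rate* (simulates an imperfect secondary classifier)."""
    rng = np.random.default_rng(seed)
    values = grid.values.copy()
    flip = (rng.random(grid.shape) < error_rate) & grid.valid_mask
    codes = np.array(grid.scheme.codes)
    values[flip] = rng.choice(codes, size=int(flip.sum()))
    return grid.copy_with(values)
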