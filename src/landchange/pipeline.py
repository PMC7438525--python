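"""End-to-end pipeline orchestration with file handoffs and a run manifest.

Every stage reads and writes files, so any stage can be re-run in isolation.
The manifest records seeds, per-stage runtimes and sha256 hashes of every
output, which makes determinism checks trivial: two runs with the same
config must produce identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import accuracy as acc
from . import change as chg
from . import drivers as drv
from . import fragmentation as frag
from .classification import ClassifierSpec, postprocess_chain, sample_training_pixels, train_classify
from .grids import (
    GridTransform,
    read_landcover,
    read_polygons,
    read_raster,
    write_landcover,
    write_polygons,
    write_raster,
)
from .synthetic import (
    ScenarioConfig,
    apply_cloud_mask,
    generate_scene_pair,
)

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("simulate", "classify", "postprocess", "accuracy", "change", "fragment", "drivers")

#: Predictors for the primary (optical-like) classifier.
PRIMARY_PREDICTORS = ("elevation", "slope", "northness", "tpi", "temperature",
                      "precipitation", "ndvi_change")
#: Reduced predictor set standing in for the secondary (radar-like) classifier.
SECONDARY_PREDICTORS = ("elevation", "slope", "northness", "tpi")


@dataclass
class PipelineConfig:
    out_dir: Path = Path("pipeline_out")
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    interval_years: float = 27.0
    scales: tuple[int, ...] = frag.DEFAULT_SCALES
    interior_threshold: float = frag.INTERIOR_THRESHOLD
    driver_fraction: float = 0.10
    driver_replicates: int = 1000
    # temperature is a deterministic lapse-rate function of elevation in the
    # synthetic scenes, so only one of the two enters the default design
    driver_covariates: tuple[str, ...] = (
        "slope", "temperature", "precipitation",
        "dist_village", "dist_town", "dist_road", "dist_river",
        "soil", "landform", "degradation",
    )
    training_pixels_per_polygon: int = 30
    validation_pixels_per_polygon: int = 10
    seeds: dict = field(default_factory=lambda: {
        "classify": 11, "accuracy": 13, "drivers": 17,
    })

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "out_dir" in raw:
            cfg.out_dir = Path(raw["out_dir"])
        if "scenario" in raw:
            sc = raw["scenario"]
            if "shape" in sc:
                sc["shape"] = tuple(sc["shape"])
            cfg.scenario = ScenarioConfig(**sc)
        if "classifier" in raw:
            cfg.classifier = ClassifierSpec(**raw["classifier"])
        for key in ("interval_years", "driver_fraction", "driver_replicates",
                    "interior_threshold", "training_pixels_per_polygon",
                    "validation_pixels_per_polygon"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "scales" in raw:
            cfg.scales = tuple(int(s) for s in raw["scales"])
        if "driver_covariates" in raw:
            cfg.driver_covariates = tuple(raw["driver_covariates"])
        if "seeds" in raw:
            cfg.seeds.update(raw["seeds"])
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_stack(out: Path):
    from .grids import CovariateStack

    layers = {}
    transform = GridTransform()
    for f in sorted((out / "covariates").glob("*.tif")):
        arr, transform = read_raster(f)
        layers[f.stem] = np.asarray(arr, dtype=float)
    categorical = frozenset({"soil", "landform", "degradation"} & set(layers))
    return CovariateStack(layers=layers, transform=transform, categorical=categorical)


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the requested stages in canonical order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "stages": [],
        "seeds": dict(config.seeds, scenario=config.scenario.seed,
                      classifier=config.classifier.seed),
        "outputs": {},
        "runtimes_s": {},
        "cell_counts": {},
    }
    stage_fns = {
        "simulate": _stage_simulate,
        "classify": _stage_classify,
        "postprocess": _stage_postprocess,
        "accuracy": _stage_accuracy,
        "change": _stage_change,
        "fragment": _stage_fragment,
        "drivers": _stage_drivers,
    }
    for stage in ALL_STAGES:
        if stage not in stages:
            continue
        t0 = time.perf_counter()
        try:
            written = stage_fns[stage](config, out, manifest)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(stage)
        manifest["runtimes_s"][stage] = round(time.perf_counter() - t0, 3)
        for f in written:
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    manifest_path = out / "manifest.json"
    payload = {k: v for k, v in manifest.items() if k != "runtimes_s"}
    payload["runtimes_s"] = manifest["runtimes_s"]
    manifest_path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(config: PipelineConfig, out: Path, manifest: dict) -> list[Path]:
    scene = generate_scene_pair(config.scenario)
    written = []
    written.append(write_landcover(scene.epoch1, out / "epoch1_true.tif"))
    written.append(write_landcover(scene.epoch2, out / "epoch2_true.tif"))
    cov_dir = out / "covariates"
    cov_dir.mkdir(exist_ok=True)
    for name, layer in scene.covariates.layers.items():
        written.append(write_raster(layer, scene.covariates.transform, cov_dir / f"{name}.tif"))
    written.append(
        write_raster(scene.cloud_mask.astype(np.float32), scene.covariates.transform,
                     out / "cloud_mask.tif")
    )
    for role, polys in scene.polygons.items():
        written.append(write_polygons(polys, scene.covariates.transform, out / f"polygons_{role}.geojson"))
    truth = {
        "scenario": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in dataclasses.asdict(scene.config).items()},
        "transition_counts": scene.truth["transition_counts"].tolist(),
        "category_labels": scene.truth["category_labels"],
    }
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True))
    written.append(truth_path)
    manifest["cell_counts"]["simulate_valid"] = int(scene.epoch1.valid_mask.sum())
    return written


def _stage_classify(config: PipelineConfig, out: Path, manifest: dict) -> list[Path]:
    stack = _load_stack(out)
    training = read_polygons(out / "polygons_training.geojson")
    seed = config.seeds["classify"]
    written = []
    cloud, _ = read_raster(out / "cloud_mask.tif")
    cloud = cloud > 0.5
    for epoch, tif in (("t1", "epoch1_true.tif"), ("t2", "epoch2_true.tif")):
        predictors = PRIMARY_PREDICTORS if epoch == "t2" else tuple(
            p for p in PRIMARY_PREDICTORS if p != "ndvi_change"  # no change layer for epoch 1
        )
        sample = sample_training_pixels(
            training, stack, per_polygon=config.training_pixels_per_polygon,
            seed=seed, predictor_names=predictors,
        )
        spec = ClassifierSpec(
            n_trees=config.classifier.n_trees,
            bag_fraction=config.classifier.bag_fraction,
            seed=config.classifier.seed,
        )
        predicted = train_classify(sample, spec, stack, epoch=epoch)
        if epoch == "t2":  # optical gaps from clouds
            predicted = apply_cloud_mask(predicted, cloud)
            sample2 = sample_training_pixels(
                training, stack, per_polygon=config.training_pixels_per_polygon,
                seed=seed + 1, predictor_names=SECONDARY_PREDICTORS,
            )
            secondary = train_classify(
                sample2, ClassifierSpec(n_trees=spec.n_trees, bag_fraction=spec.bag_fraction,
                                        seed=spec.seed + 1),
                stack, epoch=epoch,
            )
            written.append(write_landcover(secondary, out / "epoch2_secondary.tif"))
        written.append(write_landcover(predicted, out / f"{'epoch1' if epoch == 't1' else 'epoch2'}_primary.tif"))
        manifest["cell_counts"][f"classify_{epoch}_valid"] = int(predicted.valid_mask.sum())
    return written


def _stage_postprocess(config: PipelineConfig, out: Path, manifest: dict) -> list[Path]:
    dem, _ = read_raster(out / "covariates" / "elevation.tif")
    written = []
    for epoch, primary_name, secondary_name in (
        ("t1", "epoch1_primary.tif", None),
        ("t2", "epoch2_primary.tif", "epoch2_secondary.tif"),
    ):
        primary = read_landcover(out / primary_name, epoch=epoch)
        secondary = (
            read_landcover(out / secondary_name, epoch=epoch) if secondary_name else None
        )
        final = postprocess_chain(primary, secondary, np.asarray(dem, dtype=float))
        name = f"{'epoch1' if epoch == 't1' else 'epoch2'}_final.tif"
        written.append(write_landcover(final, out / name))
        manifest["cell_counts"][f"postprocess_{epoch}_valid"] = int(final.valid_mask.sum())
    return written


def _stage_accuracy(config: PipelineConfig, out: Path, manifest: dict) -> list[Path]:
    validation = read_polygons(out / "polygons_validation.geojson")
    seed = config.seeds["accuracy"]
    written = []
    for label, name in (("epoch1", "epoch1_final.tif"), ("epoch2", "epoch2_final.tif")):
        grid = read_landcover(out / name)
        rows, cols, ref = acc.sample_validation_pixels(
            validation, per_polygon=config.validation_pixels_per_polygon, seed=seed
        )
        em = acc.build_error_matrix(grid, rows, cols, ref)
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            try:
                report = acc.olofsson_estimates(em)
            except ValueError:
                report = None
        em_path = out / f"error_matrix_{label}.csv"
        em.to_dataframe().to_csv(em_path)
        written.append(em_path)
        if report is not None:
            rpt_path = out / f"accuracy_{label}.csv"
            report.to_dataframe().to_csv(rpt_path, index=False)
            written.append(rpt_path)
            manifest["cell_counts"][f"accuracy_{label}_overall"] = round(report.overall_accuracy, 4)
    return written


def _stage_change(config: PipelineConfig, out: Path, manifest: dict) -> list[Path]:
    e1 = read_landcover(out / "epoch1_final.tif", epoch="t1")
    e2 = read_landcover(out / "epoch2_final.tif", epoch="t2")
    tm = chg.transition_matrix(e1, e2)
    written = []
    tm_path = out / "transition_matrix.csv"
    tm.to_dataframe().to_csv(tm_path)
    written.append(tm_path)
    c1 = chg.aggregate_to_categories(e1)
    c2 = chg.aggregate_to_categories(e2)
    ctm = chg.transition_matrix(c1, c2)
    ctm_path = out / "transition_matrix_categories.csv"
    ctm.to_dataframe().to_csv(ctm_path)
    written.append(ctm_path)
    names = dict(zip(e1.scheme.codes, e1.scheme.names))
    written.append(chg.write_sankey_json(chg.sankey_export(tm, names), out / "sankey.json"))
    gl = chg.gain_loss_map(c1, c2, focus="forest")
    written.append(write_landcover(gl, out / "forest_gain_loss.tif"))
    forest_code = chg.category_code("forest")
    idx = ctm.labels.index(forest_code)
    a1 = ctm.row_totals()[idx] * ctm.cell_area_ha
    a2 = ctm.col_totals()[idx] * ctm.cell_area_ha
    summary = {
        "forest_area_epoch1_ha": float(a1),
        "forest_area_epoch2_ha": float(a2),
        "interval_years": config.interval_years,
        "annual_rate_pct": chg.annual_rate(a1, a2, config.interval_years)
        if a1 > 0 and a2 > 0 else None,
        "valid_cells": tm.valid_cell_count,
    }
    summary_path = out / "change_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    written.append(summary_path)
    return written


def _stage_fragment(config: PipelineConfig, out: Path, manifest: dict) -> list[Path]:
    written = []
    results = {}
    for label, name in (("epoch1", "epoch1_final.tif"), ("epoch2", "epoch2_final.tif")):
        grid = read_landcover(out / name)
        forest = grid.category_mask("forest")
        nodata = ~grid.valid_mask
        per_scale = {}
        usable = [w for w in config.scales if w <= max(grid.shape)]
        for window in usable:
            res = frag.compute_fad(forest, window, nodata_mask=nodata,
                                   cell_area_ha=grid.cell_area_ha)
            per_scale[window] = res
            written.append(
                write_raster(res.density, grid.transform, out / f"fad_{label}_w{window}.tif")
            )
        results[label] = per_scale
    summary = frag.fragmentation_summary(results["epoch1"], results["epoch2"])
    path = out / "fragmentation_summary.csv"
    summary.to_csv(path, index=False)
    written.append(path)
    return written


def _stage_drivers(config: PipelineConfig, out: Path, manifest: dict) -> list[Path]:
    e1 = chg.aggregate_to_categories(read_landcover(out / "epoch1_final.tif", epoch="t1"))
    e2 = chg.aggregate_to_categories(read_landcover(out / "epoch2_final.tif", epoch="t2"))
    stack = _load_stack(out)
    names = tuple(n for n in config.driver_covariates if n in stack.names)
    written = []
    for source in ("forest", "shrubland", "agriculture_developed"):
        try:
            obs = drv.assemble_observations(e1, e2, stack, source, covariate_names=names)
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                fit = drv.fit_subsampled(
                    obs,
                    fraction=config.driver_fraction,
                    replicates=config.driver_replicates,
                    seed=config.seeds["drivers"],
                )
        except (ValueError, RuntimeError) as exc:
            manifest["cell_counts"][f"drivers_{source}_skipped"] = str(exc)
            continue
        table = drv.relative_risk_ratios(fit)
        path = out / f"drivers_{source}.csv"
        table.to_csv(path, index=False)
        written.append(path)
        manifest["cell_counts"][f"drivers_{source}_n"] = obs.n
    return written
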