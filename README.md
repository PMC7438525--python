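# landchange

Analysis pipeline for two-epoch categorical land-cover rasters: supervised
classification post-processing, error-adjusted accuracy and area estimation,
pixel-by-pixel transition accounting with compound annual change rates,
multiscale forest-area-density (FAD) fragmentation with forest-interior
delineation, and multinomial transition-risk modelling with subsample
replication. A synthetic-landscape generator with known ground truth drives
testing and parameter-recovery checks end to end.

## Layout

| Module | Purpose |
| --- | --- |
| `landchange.grids` | Raster data model, class schemes, GeoTIFF/GeoJSON I/O, alignment checks |
| `landchange.synthetic` | Seeded two-epoch scene generator: elevation-banded classes, covariates, cloud masks, polygon sampling, known transition coefficients |
| `landchange.covariates` | DEM derivatives (Horn slope, northness, TPI), NDVI and NDVI change, Euclidean distance layers |
| `landchange.classification` | Training-pixel sampling, random-forest classification (500 trees, 2/3 bag, sqrt(p) splits), gap filling, elevation-band reassignment, 3×3 majority filter |
| `landchange.accuracy` | Error matrices and stratified error-adjusted accuracies/areas with 95% CIs |
| `landchange.change` | Category aggregation, transition matrices, compound annual rates, gain/loss maps, Sankey export |
| `landchange.fragmentation` | Summed-area-table FAD at windows 7/13/27/81/243, interior (FAD ≥ 0.9), fragmentation classes, interior-change accounting |
| `landchange.drivers` | Three-outcome multinomial logits (stay as baseline), 10% × N subsample replication, percentile CIs, relative risk ratios, probability surfaces |
| `landchange.pipeline` / `landchange.cli` | File-based stage orchestration with a hashed, seeded run manifest; `landchange` CLI |

GeoTIFF I/O is backed by `tifffile` with the standard georeferencing tags
(`ModelPixelScaleTag`, `ModelTiepointTag`, `GDAL_NODATA`), so outputs open in
common GIS software without a GDAL dependency.

## CLI

```bash
# full synthetic run: simulate -> classify -> postprocess -> accuracy ->
# change -> fragment -> drivers, with a manifest of seeds and output hashes
landchange run-all --config config.yaml --out runs/demo

# individual stages (same config/out contract)
landchange simulate --out runs/demo
landchange fragment --out runs/demo

# DEM derivatives for external rasters
landchange covariates --dem dem.tif --out cov/
```

A minimal `config.yaml`:

```yaml
scenario:
  shape: [200, 200]
  seed: 42
  cloud_fraction: 0.17
classifier:
  n_trees: 500
scales: [7, 13, 27, 81]
driver_replicates: 1000
```

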