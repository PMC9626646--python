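# habcurve

Evolving-curve habitat segmentation for multiband (Sentinel-2-style) rasters:

- **segmentation** — Lagrangian curve evolution in two modes: *automatic*
  closed-curve growth from a seed point/circle/polygon, driven by a per-band
  homogeneity range, an edge-detector braking term `g(s) = 1/(1 + K s²)` and
  curvature smoothing; and *semiautomatic* open-curve fitting between anchor
  points, attracted to image edges.
- **features** — per-segment spectral signatures (mean/min/max/std for each
  of the 14 canonical bands → 56 values per segment per date) and the
  Relative High Laplacian (RHL N%) structural classifier that separates
  heterogeneous natural stands from even-aged plantations.
- **evaluation** — mean and maximal Hausdorff distances between segmentation
  curves and GPS ground-truth tracks, per-habitat report aggregation, and a
  from-scratch one-way PERMANOVA (Euclidean / Bray–Curtis) with a
  band-combination screen.
- **synthetic_scene** — a deterministic generator of labelled multiband
  scenes (habitat blobs with per-band spectra, natural/plantation texture,
  sensor noise), ground-truth polygons, jittered GPS-like tracks and
  relevé-style seed points, used as test fixtures and for end-to-end runs.
- **raster_io / curves** — the supporting raster model (GeoTIFF I/O via
  `tifffile`, world↔pixel mapping, bilinear sampling, Gaussian smoothing,
  5-point Laplacian) and curve utilities (GPX/GeoJSON I/O, uniform
  resampling, pixel-center rasterization, shoelace areas). GPX input is
  projected WGS84 → UTM with a built-in transverse-Mercator transform; all
  distances are metric.

## CLI

```sh
habcurve simulate --seed 1 --out fixtures/            # synthetic scene + truths + GPX
habcurve info fixtures/scene.tif
habcurve segment-auto --raster fixtures/scene.tif --seed 401500,5398500 \
    --preset mixed --out seg.geojson
habcurve segment-semi --raster fixtures/scene.tif --anchors anchors.geojson \
    --out seg.geojson
habcurve features --raster fixtures/scene.tif --segments seg.geojson \
    --date 2019-08-31 --out features.csv
habcurve rhl --raster fixtures/scene.tif --segments seg.geojson \
    --band B04 --pct 10 --out rhl.csv
habcurve hausdorff --a seg.geojson --b fixtures/tracks.gpx --crs EPSG:32634
habcurve report --pairs distances.csv --out table.csv
habcurve permanova --features wide_features.csv --group habitat \
    --distance euclidean --perms 9999 --seed 7
```

`segment-*` accept a JSON/YAML `--config` overriding any
`SegmentationParams` field (driving bands, homogeneity range, weights, time
step, vertex spacing, stopping rule).

## Conventions

- North-up, square-pixel rasters only; all bands on one common grid
  (10 m default). Pixel centers sit at half-integer offsets; sampling is
  bilinear in world coordinates.
- Signature std is the population standard deviation.
- RHL uses the absolute Laplacian of the smoothed band; a perfectly flat
  region has RHL = 0 by convention.
- PERMANOVA z-scores columns for Euclidean distance and min–max rescales
  them to [0, 1] for Bray–Curtis; p-values use the +1 permutation
  correction.
- The segmentation engine is deterministic: identical inputs and parameters
  produce bit-identical curves.
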