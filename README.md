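# cropxfer

Cross-year reuse of crop training samples for satellite time-series
classification. Given labeled sample points from a historical year and
multi-date, four-band (blue/green/red/NIR) imagery for both the
historical and a target year, `cropxfer`:

1. fits a continuous **feature curve** (cubic polynomial, 3-parameter
   Gaussian, or 5-parameter annual harmonic — selected per feature by a
   2/3–1/3 train/test comparison on R²/RMSE) to each pixel's irregular
   seasonal series of NIR, NDVI and NDWI;
2. scores every pixel in each sample's 5×5 target-year neighbourhood by
   **dynamic-time-warping similarity** of the resampled curves,
   `S = exp(-D / max(m, n))`, and keeps the single most similar pixel as
   a *potential sample* carrying the historical crop label;
3. **screens** potential samples per crop with k-means clustering on
   curve summary statistics (mean, SD, min, max, quartiles), choosing
   the cluster count by silhouette coefficient and retaining the
   majority cluster as *generated samples*;
4. trains a **random forest** (150 trees, √p features per split,
   full-size bootstrap) on curve evaluations over a fixed DOY grid and
   classifies the target-year scene;
5. reports **OA / per-class PA / UA / F1** from a confusion matrix with
   a stratified 70/30 validation split.

A first-class synthetic scene generator (`cropxfer.synthetic_scene`)
simulates multi-year scenes with crop-specific double-logistic NDVI
phenology, per-field sowing/vigor variability, inter-annual phase
shifts, cloud gaps and configurable crop rotation, so the whole chain
is testable end to end without external data.

## CLI

All stages are exposed through one entry point:

```bash
cropxfer simulate         --config scene.yaml --out scenes/
cropxfer generate-samples --hist-scene scenes/2017 --target-scene scenes/2018 \
                          --samples scenes/samples_2017.csv --window 5 \
                          --out potential.csv --skip-log skips.csv
cropxfer screen           --potential potential.csv --out generated.csv \
                          --report screening.json --kmax 20 --seed 7
cropxfer train            --samples generated.csv --scene scenes/2018 --out model.joblib
cropxfer classify         --model model.joblib --scene scenes/2018 --out map.tif
cropxfer evaluate         --pred map.tif --truth scenes/samples_2018.csv --out report.json
cropxfer run              --config pipeline.yaml --out run/
cropxfer summarize        run1/ run2/
```

`cropxfer run` drives the whole experiment from one YAML config
(scene geometry, historical-year schemes, window/cluster/forest
settings, per-stage seeds) and writes every artifact plus a manifest
with a config hash into the run directory. Scenes are stored as
per-date float32 TIFFs (NaN = nodata) with a `scene.json` sidecar
carrying the year, DOY list, band order and geotransform; samples
travel as CSV or GeoJSON.

## Package layout

| module | responsibility |
| --- | --- |
| `cropxfer.synthetic_scene` | multi-year synthetic scenes, ground truth, sample drawing |
| `cropxfer.raster_io` | scene/sample/label I/O, DN→radiance conversion |
| `cropxfer.feature_curves` | NDVI/NDWI, curve fitting, fit statistics, model selection |
| `cropxfer.similarity_transfer` | DTW, curve similarity, potential-sample selection |
| `cropxfer.sample_screening` | summary features, k-means, silhouette, majority-cluster screening |
| `cropxfer.classification` | feature matrices, random forest, scene classification |
| `cropxfer.evaluation` | 70/30 split, confusion matrix, OA/PA/UA/F1 |
| `cropxfer.pipeline` | experiment orchestration, manifests, run summaries |
| `cropxfer.experiments` | seeded end-to-end recovery benchmarks |
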