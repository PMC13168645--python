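# peatwatch

Long-term peatland landscape monitoring from annual satellite composites,
exercised end-to-end on a synthetic raised-bog landscape generator so every
stage is testable against known ground truth.

The pipeline covers:

- **synthetic** — synthetic monthly hydroclimate (seasonal cycle + trend +
  noise, with `cwb = ppt - pet` exact by construction) and a three-class
  landscape (Forest / Bog / Grassland) with stochastic, climate-modulated
  bog-to-forest encroachment at the forest edge, rendered to multi-band
  reflectance + thermal scenes with QA cloud flags.
- **preprocess** — QA bit decoding, Level-2 product scaling, seasonal scene
  selection (June with fallback to June–August) and per-pixel medoid
  compositing (composite spectra are always observed spectra).
- **indices** — NDVI / NDMI / NBR / MNDWI, Tasseled-Cap wetness with
  per-sensor coefficient sets, NDBSI = (SI + IBI)/2 (two SI variants),
  brightness temperature and single-channel or product-derived LST.
- **landcover** — two-stage training (maximum-likelihood seed classification,
  stable-pixel masks, balanced point sampling), seeded Random Forest, 75/25
  hold-out accuracy with stratified confusion-matrix metrics (OA, kappa,
  UA/PA, Type I/II, F1), 5-year majority filtering, class-area accounting and
  Markov transition matrices (start-to-end or pooled-annual).
- **rsei** — per-year covariance PCA of normalized NDVI/WET/NDBSI/LST into a
  [0,1] ecological condition index with an explicit orientation contract
  (positively correlated with greenness/wetness, negatively with
  dryness/heat), five 0.2-wide categories and class-stratified summaries.
- **trends** — Theil–Sen slope with rank-based 95% CI, Mann–Kendall test with
  tie-adjusted variance, lag-1 autocorrelation screening with a
  variance-corrected MK test as the default remedy (Yue–Pilon trend-free
  prewhitening also available), climate aggregation, anomalies and
  class-level climate/condition correlations.
- **change** — end-minus-start delta mapping, configurable change thresholds,
  distributional summaries and connected-component patch statistics.
- **pipeline / cli** — one-config orchestration of all stages with a single
  master seed and a written run report.

## CLI

```bash
peatwatch run-all --seed 1 --out runs/demo          # full synthetic pipeline
peatwatch simulate --seed 1 --out runs/sim          # climate CSV + truth maps
peatwatch classify --n-train 300 --n-trees 200 --out runs/cls
peatwatch rsei --variant table_verbatim --out runs/rsei
peatwatch trends --climate-csv runs/sim/climate.csv --out runs/trends.csv
peatwatch change --start runs/rsei/rsei_first_1984.tif \
                 --end runs/rsei/rsei_last_2024.tif \
                 --rule std_multiple:0.5 --connectivity 8 --out runs/chg
```

A YAML config (see `peatwatch.pipeline.PipelineConfig.to_yaml`) controls grid
size, years, class spectra, encroachment/cloud parameters and every stage
setting; the resolved config is written beside the outputs of each run.

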