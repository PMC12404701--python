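# benthotrend

Analytics for video-based monitoring of benthic invertebrate communities.

Long-term ROV footage of hard-substrate habitats (rock walls, steep
slopes) can be turned into quantitative ecology once an object-detection
model has counted animals in every frame. `benthotrend` implements the
full chain from per-frame detection tables to ecological conclusions:

* **Detector evaluation** — recall `R = TP/(TP+FN)`, precision
  `P = TP/(TP+FP)`, `F1 = 2PR/(P+R)` as functions of the confidence
  threshold, per-class average precision `AP = Σ_r P(r)·ΔR(r)` and its
  unweighted mean over classes (mAP), plus a normalized confusion matrix
  with a background row/column.
* **Depth registration** — sparse, partly corrupt depth-overlay readings
  are validated (plausibility window, step-outlier rule), linearly
  interpolated on frame index, and rounded to integer metres.
* **Darwin Core occurrence construction** — detections are confidence
  filtered (default ≥ 0.60), zero-expanded so every (frame, taxon) pair
  exists, and aggregated per (transect, taxon, depth) into mean count
  per frame and max count, conserving detection totals exactly.
* **Depth distributions** — a taxon's depth distribution is summarised
  by the 50th percentile of its abundance-by-depth profile with the
  16th/84th percentiles as bounds of the central 68 % of detections
  (μ ± 1σ under normality); the same statistic on a national occurrence
  download (depths repeated by `individualCount`) gives the comparison.
* **Thermal niche** — each taxon's preferred temperature is the median
  seafloor temperature over its worldwide occurrences after four
  filters: within-cell temperature range > 2 °C, coordinate uncertainty
  > 100 m, nearest-neighbour isolation > 3000 km, and 1 km spatial
  thinning by seeded random retention.
* **Abundance trends** — a Gaussian identity-link GLM of z-scored
  abundance on z-scored `year`, `day`, `day²`, `√depth`, `depth`, per
  taxon and per trait group; the scaled-year coefficient is the taxon's
  abundance trend.
* **Trait drivers** — standardized linear regression of abundance
  coefficients on median temperature (slope ≡ Pearson r) and exact
  Wilcoxon rank-sum tests for binary size/lifestyle traits.

A seeded synthetic-data generator emulates the entire survey structure
(unimodal depth profiles, year trends, seasonality, detector noise,
corrupted depth overlays, contaminated global occurrence sets over a
synthetic temperature raster) so every stage is testable against known
truth without any downloads.

## Worked example

```python
from benthotrend import io, pipeline

cfg = io.PipelineConfig(out_dir="run", seed=5)
manifest = pipeline.run_pipeline(cfg)   # simulates inputs, runs all stages
```

`run/depth_distributions.csv` then holds the modeled depth
distributions — for the default six-taxon community the planted depth
optima (17, 36, 70, 71, 90, 94 m) are recovered as the medians:

```
                  taxon   source  median_m  lower_m  upper_m    formatted
        Acesta excavata  modeled      90.0     82.0     97.0   90 (82-97)
    Alcyonium digitatum  modeled      17.0     12.0     23.0   17 (12-23)
   Caryophyllia smithii  modeled      36.0     29.0     43.0   36 (29-43)
        Geodia barretti  modeled      71.0     59.0     83.0   71 (59-83)
            Munida spp.  modeled      94.0     87.0    100.0  94 (87-100)
     Protanthea simplex  modeled      70.0     60.0     80.0   70 (60-80)
```

and `run/drivers.csv` the trait-driver tests. With this seed the
standardized regression of the six year-coefficients on median
preferred temperature gives estimate = r = 0.832 (p = 0.0399): the
generator's warm-adapted taxa were planted with increasing abundances
and the cold-adapted ones with declines, and the driver analysis
recovers exactly that gradient. The size trait (2 large vs 4 small
taxa) gives an exact rank-sum p of 0.100, and lifestyle p = 1.0 — with
six taxa only the continuous driver has real power.

Each stage is also available separately (library functions or the
`benthotrend` CLI: `simulate`, `evaluate-model`, `register-depth`,
`build-occurrences`, `depth-profiles`, `thermal-niche`, `trends`,
`drivers`, `run-all`).

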