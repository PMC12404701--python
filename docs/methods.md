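# Methods

## The analysis chain

The package models a monitoring design in which an object detector has
been applied to archived ROV transect footage of a single site, so that
every frame carries a count (possibly 0) of each of a fixed set of
invertebrate taxa. One *transect* is one continuous filming pass; the
depth gradient of the site (defaults assume roughly 7–105 m with a
plausibility ceiling of 250 m) is traversed within a transect, and the
depth visible in the video overlay is sampled sparsely and imperfectly.

Stages and their contracts:

1. **Depth registration.** Readings are classified parsed / missing /
   rejected. Rejection reasons are: outside the plausibility window
   `(0, 250] m`, or a *step outlier* — a reading that jumps more than
   `max_step` (default 10 m) from both neighbouring valid readings
   while those neighbours agree with each other within `2·max_step`.
   The mutual-agreement clause prevents a spike from condemning its
   innocent neighbour; at the sequence ends the single neighbour must
   itself be locally consistent before it can condemn the endpoint.
   Accepted readings are linearly interpolated on frame index; frames
   outside the accepted span are excluded rather than extrapolated;
   depths are rounded half away from zero to integer metres.
2. **Occurrence construction.** Detections below the operating
   confidence threshold (default 0.60, kept when equal) are dropped
   *before* counting; the table is zero-expanded so that every
   (frame, taxon) pair exists; counts are aggregated per
   (transect, taxon, integer depth) into `mean_count` (detections per
   frame), `max_count`, and `frames_at_depth`. By construction
   `Σ_depths mean_count · frames_at_depth` equals the transect's
   post-filter detection total for the taxon, exactly. Absence records
   (mean 0) are retained — zeros are information for the trend model —
   and flagged `absent` on Darwin Core export. Occurrence IDs are
   SHA-1 hashes of (dataset, transect, taxon, depth), so identical
   inputs yield identical IDs.
3. **Depth distributions.** Abundance (mean detections per frame per
   metre of depth) is pooled across transects frame-weighted:
   `abundance(d) = Σ_t mean·frames / Σ_t frames`. A per-frame rate is
   naturally supported by frame counts, which is why pooling weights by
   frames rather than averaging per-transect profiles. Percentiles use
   the lower-step inverse of the discrete weighted CDF (smallest depth
   whose cumulative fraction reaches q/100): reproducible on
   integer-metre data, invariant to positive scaling of abundance, and
   identical to the percentile of the unit-expanded multiset when
   weights are integers. National distributions treat a missing
   `individualCount` as 1 and repeat each depth `individualCount`
   times; the study's own records are excluded by `datasetKey`.
   Interval comparison is on closed intervals: touching bounds overlap.
4. **Thermal niche.** Four filters in the order range → uncertainty →
   isolation → thinning; all boundary comparisons are strict
   (range exactly 2 °C kept, uncertainty exactly 100 m kept). Missing
   coordinate uncertainty is retained — only values *exceeding* the
   limit are grounds for removal. The isolation filter is a single pass
   against the pre-removal set, so two mutually isolated conspecifics
   remove each other; a singleton species has no neighbour and is
   removed. Thinning repeatedly picks a random unprocessed occurrence,
   retains it and deletes conspecifics within 1 km; the retained set
   has all pairwise great-circle distances above the radius and is
   deterministic given the seed. Distances are haversine on a sphere of
   radius 6371 km; at these thresholds (1–3000 km) the sub-percent
   ellipsoidal error is immaterial. Temperature categories are made
   half-open — low < 8.5 °C ≤ medium < 11 °C ≤ high — because the
   conventional printed ranges (low 5–8, medium 9–11, high 11–12)
   leave a gap at 8–9 and an overlap at 11.
5. **Trend model.** Gaussian identity-link GLM (ordinary least squares
   via statsmodels) of z-scored abundance on z-scored `year`, `day`,
   `day²`, `√depth`, `depth`. `day²` is squared on the raw day of year
   and then scaled as its own predictor. All scalings use the sample
   standard deviation (ddof = 1), matching the default of R's
   `scale()`; a constant predictor raises an error naming the column.
   A scaled, continuous response is incompatible with a count family,
   which is why the fit is Gaussian. Standard errors come from the
   unbiased residual variance; a response that fits exactly is flagged
   `degenerate` (SEs 0, p-values withheld). Trait-level trends sum the
   member taxa's mean counts within each (transect, depth) record —
   the pooled per-frame rate of the group — then scale and refit; a
   switch to averaging instead of summing only rescales the response
   and leaves z-scored fits unchanged, so summing is the default.
6. **Drivers.** The regression of per-taxon year coefficients on
   median temperature standardizes both variables by default, making
   the slope estimate equal to Pearson r. The Wilcoxon rank-sum test
   uses midranks, full enumeration of all C(n, n₁) assignments when
   both groups have ≤ 10 members and the data are tie-free
   (p = 2·min(P(W ≤ w), P(W ≥ w)), capped at 1), and otherwise a
   normal approximation with continuity and tie corrections; a fully
   tied sample yields p = 1. All tests are two-sided and uncorrected
   for multiplicity across the three drivers.

## Detector evaluation

Matching is greedy in descending confidence with one-to-one assignment
to the unmatched same-class truth of highest IoU ≥ 0.5 (configurable);
evaluation protocols for archived surveys rarely state their matching
rule, so this standard, reproducible one is documented rather than
guessed. Degenerate ratios use P = 0 when TP+FP = 0, R = 0 when
TP+FN = 0, F1 = 0 when P+R = 0, keeping curves bounded at extreme
thresholds. AP uses raw precision at each distinct-confidence step times
the recall increment — no 11-point sampling, no monotone interpolation —
and predictions sharing a confidence enter together, since no threshold
can separate them; this makes the statistic identical to brute-force
threshold enumeration. The confusion matrix runs a second,
class-agnostic matching pass over first-pass leftovers to attribute
cross-class confusion, with background absorbing residual FP/FN.

## The synthetic-data generator

The generator defines the conditions under which the pipeline is
validated; its defaults are fixed, not tuned.

* **Survey.** Expected detections per frame follow
  `λ = base_rate · exp(a₁·year_s + a₂·day_s + a₃·day²_s) ·
  exp(−(d−μ)²/2σ²)`: a log-linear trend times a Gaussian depth profile,
  so the analytic depth quantiles are normal quantiles
  (μ + σ·z_{0.16/0.5/0.84}) and the planted trend coefficients live on
  the scaled-covariate scale stored with the truth. Counts are Poisson;
  detector imperfection is binomial thinning (recall) plus binomial
  relabelling (confusion). The noise-free `expected` mode emits
  fractional counts equal to `λ·recall` so per-depth means reproduce
  the analytic rate curve *exactly*. Depth readings appear every 25
  frames by default with 5 % dropouts and 2 % misreads planted as an
  implausible 999 m; the first and last readings are protected so the
  interpolation span always covers the transect. The default community
  has six taxa with optima spanning 17–94 m, baseline rates 0.4–2.0
  detections/frame, year slopes ±0.04–0.15 per scaled year and recalls
  0.85–0.9 — the magnitudes a detector-based survey of a fjord wall
  community plausibly produces — over 40 transects (1997–2009 sparse,
  2015–2023 denser) at 10 frames per metre.
* **Linear-response mode.** The OLS trend model applied to
  Poisson/log-link abundances is deliberately misspecified (that is the
  field situation), so confidence-interval *coverage* cannot be nominal
  there. Coverage and type-I-error checks therefore use
  `simulate_linear_abundance`, which plants coefficients in the exact
  Gaussian linear model on a survey design matrix; the Poisson survey
  path is used for depth-percentile and rate-curve recovery instead.
* **Global occurrences.** The synthetic raster is a 0.5° grid with
  temperature linear in latitude (20 °C south to 0 °C north, about
  0.067 °C per row), a benign within-cell range of 0.5 °C, and a block
  of flagged columns with a 3 °C range. Clean points target
  temperatures drawn Normal(optimum, sd) truncated at ±3σ, one point
  per cell (cells are ≈ 55 km, so thinning never touches clean points
  and isolation never fires on them). Contaminants are labelled in a
  `contaminant` column so tests can assert exact removal sets:
  uncertainty 150–1000 m, placement in flagged high-range cells,
  isolated points ≥ 3000 km from the clean band and from each other
  (geometry caps them at 3 per species), and sub-kilometre clusters
  that thinning must collapse to one point. The truth stores the clean
  median cell temperature.
* All randomness flows through one seeded `numpy` Generator per
  dataset; a fixed seed reproduces every output byte for byte.

## Problem sizes

Validation runs at desk scale by choice: depth-percentile recovery uses
one 100 m transect at 200 frames per metre (20 000 frames, ~50 000
detections); niche recovery uses 500 clean occurrences plus 43 planted
contaminants; GLM coverage uses 200 replicates on a 300-row design and
the null rate 400 replicates; the oracle sweep uses 50 random detection
benchmarks. The full default pipeline runs in seconds.

## Known limitations

* The generator does not simulate images or box geometry realism —
  detection benchmarks are laid out on a non-overlapping grid, so
  matching ambiguity from crowded scenes is exercised only by the
  dedicated overlap tests, not at benchmark scale.
* Passing tests show the chain recovers parameters under the generator's
  assumptions (unimodal Gaussian depth profiles, log-linear trends,
  independent Poisson counts, misreads outside the plausibility
  window). Real footage adds autocorrelation along transects, occlusion
  and lighting-driven detection bias, and OCR misreads *inside* the
  plausible range; none of these are claimed to be handled.
* National-comparison and GBIF readers handle the documented column
  set; taxonomic name resolution is out of scope.
* The temperature raster is a plain lat/lon NetCDF grid; projected
  rasters and GeoTIFF are not read.
* Isolation filtering and thinning are O(n²) per species in memory;
  fine up to a few tens of thousands of occurrences per species.
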