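# Methods

This note documents the models and procedures grassmap implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic test bed does and does not demonstrate.

## The synthetic world

The generators in `synthio` exist so that every downstream stage has a
known ground truth. They emulate the *structure* of the real inputs —
cadence, band count, QA semantics, tile geometry, product legends — not
their radiometric physics.

- **Landscape.** A seeded Voronoi patchwork of the three classes on a
  ~30 m analysis grid (EPSG:4326, pixel 0.00025°). Patches are assigned
  to classes largest-first against the requested area targets, so
  empirical class fractions track the request closely (±0.05 is asserted
  at 200×200). The landscape is temporally static; inter-annual class
  change is out of scope of the test bed.
- **Reflectance.** Per class and band, a seasonal sinusoid
  `mean + amplitude·sin(2π(doy − phase)/365)` plus i.i.d. Gaussian pixel
  noise, clipped to [0, 1]. The documented `easy` preset separates the
  classes by NDVI profile alone: other land stays near NDVI 0, cultivated
  grassland swings ~0.1–0.8 through the season (management cycles),
  natural grassland holds NDVI ≳ 0.55 year-round. Noise sd is 0.01
  (`noisy` preset: 0.05). These are invented presets — no per-class
  spectral statistics of real training data are published to calibrate
  them against.
- **Clouds.** Spatially correlated blobs: a Gaussian-smoothed noise field
  (σ = 6 px) thresholded at the acquisition's cloud fraction, which is
  jittered around the requested probability (exact at the 0 and 1
  limits). Correlated gaps are what make the seasonal gap-filler's job
  non-trivial; i.i.d. pixel clouds would be much easier.
- **Reference tiles** are 1×1 km blocks relabeled on a 10 m grid by
  nearest neighbour from the landscape, one label grid and one uniform
  random reference date per source within that source's year range
  (sources have era-specific coverage, e.g. 2009–2014 vs 2019–2022).
- **Mock products** render the truth through three different
  grassland-like legend classes (grassland / short vegetation /
  herbaceous) against three conflicting classes, with an independent
  per-(product, epoch, pixel) disagreement flip.

Passing tests on this world shows the pipeline machinery is correct and
that the chain can recover a signal it is designed for. It does not show
skill on real imagery: no atmospheric effects, no mixed pixels at 30 m,
no label noise from interpreters, no class change over time.

## Compositing and gap-filling

- QA codes {3, 4, 7, 8, 9, 10} are removed; {1, 2} are clear-sky. The
  sets are configurable and must be disjoint.
- 8-bit encoding maps a configured reflectance interval (default [0, 1],
  one interval for all bands including thermal) linearly to 0–250,
  rounding half away from zero — the symmetric treatment of both range
  ends. 255 is reserved for no-data.
- Bi-months are the calendar pairs Jan–Feb … Nov–Dec. Aggregation weights
  each acquisition by `1 − cloud_cover`; when every clear observation of
  a pixel happens to carry weight 0 (fully clouded acquisitions), the
  plain mean of those observations is used rather than discarding them.
- SWAG weights: `w(L, Δp) = s · 0.5ᴸ` with `s = 1` for the same
  bi-month, `0.25` for cyclically adjacent bi-months, `0` otherwise;
  `L` is the year lag. This is one admissible reading of the published
  description (the exact vector lives in cited external work); the decay
  and period weights are configurable. Only *observed* (never previously
  imputed) composites strictly earlier in time are eligible, so imputed
  values are causal: changing any later acquisition cannot change them.
  A property test checks equality with a brute-force re-implementation on
  random series.

## Indices

Formulas are the standard ones (see README). Open choices:

- **NDWI** uses the NIR/SWIR1 (vegetation water) form.
- **FAPAR** is `clip(1.24·NDVI − 0.168, 0, 1)`; the linear NDVI
  relationship is stated but its coefficients are not printed, so they
  are configuration with this documented default.
- Index 8-bit storage maps each index's configured analytic range to
  0–250 (EVI uses [−2, 2]; the normalized-difference indices [−1, 1]);
  BSF is stored as `round(BSF·100)`.
- BSF uses a strict `NDVI < 0.35` and, with missing periods, counts over
  the available periods only; an all-missing year is no-data.

## Sampling design and reference processing

- **FSCS**: layers are z-scored (the scaling is not specified in the
  source; z-scores are the conventional choice), PCA retains the leading
  components up to 75 % explained variance capped at 10, k-means is
  seeded, and each cluster returns the unmasked pixel nearest its centre.
  Distinctness across clusters is enforced by falling through to the
  next-nearest pixel, and an exhaustive-scan oracle verifies the argmin.
- **60 m support**: footprints of 6×6 ten-metre cells pave each tile from
  its origin; partial edge footprints are dropped. The footprint class is
  the modal cell class; only proportion-1.0 candidates survive as
  training points. Candidates from different sources are independent —
  the processing never reconciles sources within a footprint.
- **Temporal augmentation** requires equal classes from two different
  sources with a year gap strictly below 5 (a 2010/2014 pair fills
  2011–2013; 2010/2015 fills nothing), consistent with a minimum 5-year
  rotation period. Duplicated replicates from overlapping pairs collapse
  to one per (location, year, class).
- **Product-agreement filter**: the reading "two products in two years"
  is implemented as ≥2 distinct products *each* conflicting in ≥2
  distinct epochs (symmetric for non-grassland points against
  grassland-like classes). The laxer pooled reading (≥2 product-epoch
  pairs in total) is available behind `count_product_epoch_pairs`.

## Modelling

- Feature space: 84 seasonal features (7 bands on their 8-bit scale + 7
  indices on the analytic scale, × 6 periods) plus the static layers.
  Rows with any missing feature are flagged and dropped before fitting,
  with counts available to the caller.
- Calibration split: per tile, `round(0.10·n)` samples (half-up), but a
  tile never loses its last training sample.
- Folds: tiles are shuffled with the given seed and dealt round-robin
  into 5 folds; samples inherit their tile's fold. This is the spatial
  blocking that keeps same-tile samples out of a model's test side.
- RFE drops the `step = 4` least important features per forest fit
  (impurity importance, stable sort) until exactly `target = 75` remain
  (fewer dropped on the final iteration).
- Successive halving starts at 500 calibration samples, scores surviving
  candidates by tile-blocked CV log-loss, keeps the better half
  (rounding up) and doubles the subsample each round.
- The default learner is a 60-tree random forest; gradient boosting and
  a multilayer perceptron are available through the same `ModelSpec`
  surface for learner comparisons.
- The probability skill score is `1 − LL_model / LL_baseline` with the
  baseline predicting the class prevalence; probabilities are clipped at
  1e−15. The exact form in the source's citation is not printed, so this
  definition is documented configuration.

## Thresholds, smoothing, integration

- The PR curve is evaluated at every distinct predicted probability
  (`score ≥ t` counts positive). The balanced threshold minimizes
  `|precision − recall|`, ties breaking toward the lower threshold
  (favouring recall, since validation of such maps typically shows
  omission error). Because every cutoff between two consecutive distinct
  scores yields identical confusion counts, the *returned* cutoff is the
  midpoint of that equivalence interval — the standard split-point
  convention. This matters in the near-separable regime: the minimizing
  observed score can be 1.0, and deploying `p ≥ 1.0` on smoothed cubes
  would contradict the recall-favouring intent, while the midpoint is
  confusion-identical on the calibration data.
- The 3-D Savitzky–Golay filter fits a trivariate polynomial (per-axis
  degree 3) over a 5×5×5 (year, row, col) window by least squares — the
  "squared window with five pixels" is read as 5 along every axis, and
  the window/order are arguments. On complete windows the tensor-product
  fit factorizes exactly into three 1-D passes, which is how it is
  computed; near edges the window shifts inside the cube and the
  polynomial is evaluated at the true pixel position; windows touching
  no-data pixels are recomputed with an explicit masked fit (pixels with
  fewer valid neighbours than basis terms keep their raw value). Cubes
  shorter than the window in time fall back to the largest odd window
  with a warning. Output is clipped to [0, 100] and re-quantized;
  no-data stays 255.
- MADi is the per-pixel mean over years of |raw − smoothed|, skipping
  years where either cube is no-data.
- Dominant integration applies the calibrated thresholds inclusively to
  probabilities/100; pixels reaching both thresholds take the priority
  class (default natural/semi-natural, the class with the higher
  cross-validated F1); no-data propagates from either cube.
- The stability index divides by the previous year's value by default;
  the pair-mean denominator is selectable. Zero denominators flag the
  pair as undefined rather than erroring.

## Raster products and naming

All product rasters are uint8 GeoTIFFs, nodata 255, EPSG:4326, pixel
0.00025°, internally tiled with overview pyramids (nearest-neighbour
resampling for class layers, nodata-aware averaging for probability
layers). Filenames join ten lowercase fields with underscores: project,
class, procedure, variable (p/c), resolution, begin date, end date,
extent, CRS, version — the printed examples fix the tokens, the
underscore joining is this package's convention, and
`parse(build(fields)) == fields` is tested. The source text announces
nine fields but lists ten; all ten are implemented.

GeoTIFF georeferencing is written directly through the standard tags
(ModelPixelScale, ModelTiepoint, a minimal GeoKeyDirectory for EPSG:4326,
GDAL_NODATA) on top of tifffile, and the reader restores arrays
bit-exactly.

## Problem sizes

The end-to-end run (`pipeline.run_end_to_end`) uses a 150×150 px
landscape, 7 years × 23 acquisitions, 12 reference tiles capped at 60
samples each, and 60-tree forests — chosen so a full chain executes in
well under a minute while every stage operates above its degenerate
minimum (≥5 tiles for blocking, ≥5 years for the temporal window).

## Known limitations

- The synthetic landscape has no temporal class change, so the temporal
  augmentation and stability metrics are exercised on stable truth only.
- A single reflectance encoding interval is applied to all bands; a real
  thermal band would need its own configured range.
- The exclusion mask is a generic boolean raster; no real desert/ice/
  water products are consumed.
- Headline accuracies of the original global product are not reproduced
  here: they depend on millions of real reference samples and a
  multi-terabyte covariate archive. The package verifies the procedure,
  not the published numbers.
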