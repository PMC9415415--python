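# Methods

## Observation model

All reflectance is Sentinel-2 L2A surface reflectance on unit scale (digital
numbers / 10⁴), so band values live in [0, 1] and the WDVI emergence
threshold of 0.005 is meaningful. A plot's feature on a date is the zonal
mean over its sampling unit — a cluster of 8–10 pixels for the survey cycle,
or the whole plot polygon for the test cycle; both paths share the same
feature code.

The soil line is the linear bare-soil relation B8A = a·B4 with intercept 0.
Its slope is estimated as a **ratio of sums** over bare-land plots,
a = Σ B8A_i / Σ B4_i — deliberately not a regression slope and not a mean of
per-plot ratios. The ratio of sums is exact on noiseless colinear inputs,
scale invariant, and defined even for zero-variance input; it underlies
WDVI = B8A − a·B4, which is ~0 on bare soil and grows with green cover.
NDVI is computed alongside; a non-positive B8A + B4 denominator is treated
as corrupt input (it cannot occur in real L2A data) and raises.

## Lagged stacking

Analysis happens only on cloud-free scene dates — no interpolation, gap
filling or compositing. For each lag of the chosen combination (C1: 0/30/60,
C2: 0/30, C3: 0/15/30, C4: 0/15 days) the nearest cloud-free scene within a
tolerance (default ±5 days, one revisit period) is selected; ties break
toward the earlier scene for determinism; if any lag is unserved the
(date, combination) pair is infeasible. Records are scene-major — the
current scene's 11 descriptors (B2…B12, NDVI, WDVI) first, then each older
scene's — giving 22 or 33 descriptors.

The emergence filter drops a record if **any** of its scenes has
WDVI < 0.005: such a scene shows bare ground (pre-sowing or post-harvest),
and the classifiers are meant to be trained and applied on standing crops
only. The threshold value itself counts as emerged. A stricter variant that
inspects only the lagged (pre-analysis) scenes is available via
`filter_scope="lagged"`; filtering all scenes is the default because a
harvested plot at the analysis date is equally not a standing crop. Raising
the threshold is monotone non-increasing in survivors.

Training analysis dates follow a 30-day schedule (7 Apr, 7 May, 6 Jun,
6 Jul, 5 Aug, 4 Sep) intersected with each combination's feasibility, so a
fully covered plot contributes up to four records for the long-lag scheme —
one per phenological stage — and up to five for the short-lag schemes.

## Classifiers

* `PolySVMClassifier`: one binary soft-margin SVM per class pair with kernel
  k(x, xᵢ) = (xᵀxᵢ + 1)³ — raw inner product, offset c = 1, degree 3, no
  kernel-scale normalisation; descriptor standardisation (fit on training
  data only) provides all scaling. Box constraint C defaults to 1 and is
  exposed. Prediction aggregates pairwise votes; ties fall back to the
  per-class sum of signed decision values, then to class order. The binary
  machines are scikit-learn `SVC`s; the one-vs-one aggregation and tie-break
  chain are implemented here so that the rule is explicit and deterministic.
* `BaggedTreesClassifier`: 100 bootstrap-resampled, fully grown
  classification trees (library defaults for depth/leaf size; only the
  ensemble size is prescribed), majority vote, seeded via `random_state`.
  Standardisation is kept for interface parity; trees are scale invariant.

Class weighting is off by default: the strong corn/alfalfa/bean imbalance is
part of the study conditions and the resulting weakness on the rare bean
class is an expected behaviour, not a defect. Five-fold stratified
cross-validation (`cross_validate`) reports per-fold and pooled OA/kappa;
the pooled confusion matrix concatenates all held-out folds. Models persist
to a self-describing versioned joblib file; load → predict round-trips
bit-identically.

## Accuracy assessment

OA = 100·trace/total; producer's accuracy is per-true-class recall and
user's accuracy per-predicted-class precision, both in percent; an empty row
or column yields NaN ("not available") rather than 0 so aggregates are not
biased. Cohen's kappa uses p_e = Σ row_i·col_i / n²; a single-cell matrix
(p_e = 1) raises. Altman bands are implemented as half-open intervals with
upper edges 0.20 / 0.40 / 0.60 / 0.80 / 1.0 (the printed band edges leave
(0.20, 0.21) uncovered; continuity at the edges reproduces all worked
examples), negatives rating as poor. `timeline_evaluate` applies
previously trained per-combination models to a new cycle date by date
without retraining; infeasible (date, combination) pairs contribute no row,
which reproduces the varying per-date combination availability of a
cloud-limited season.

## Synthetic study system

The generator emulates the irrigation module the method was designed for;
its defaults are the study conditions, not tuning knobs.

* **Crop pattern.** Priors corn 67.2 %, alfalfa 22.5 %, bean 5.9 %, other
  4.4 %. The `survey2019` preset fixes exact counts 154/72/54 (280 plots)
  with a stratified 140/140 train/validation split (77/36/27 per half); the
  `cycle2020` preset fixes 590 corn / 264 alfalfa / 41 bean (895 plots).
  "Other" crops are generated under the priors path but excluded from
  training labels by default.
* **Phenology.** Cover trajectories are logistic rises to a crop peak with
  exponential senescence — the field data constrain only the qualitative
  pattern, so the functional form is a package choice held in presets. Corn:
  sown DOY 91–135 (uniform; sowing staggering is real but its distribution
  unrecorded), emergence lag 8 d, half-cover at 45 d, peak 0.92, senescence
  from 140 d, harvest DOY 270. Bean: sown DOY 91–120, half-cover 30 d, peak
  0.85, harvested DOY 188 (early July, grain filling). Alfalfa: perennial
  sawtooth with 56-day (8-week) cut interval, residual cover 0.15, regrowth
  rate 0.08/d, anchor staggered DOY 60–116.
* **Spectra.** Reflectance is a per-pixel linear soil/vegetation mixture
  with iid Gaussian noise (sd 0.01 per band) averaged over the unit's
  pixels. The soil endmember sits exactly on the B8A = 1.62·B4 line;
  per-crop canopy endmembers differ modestly (alfalfa densest in red edge
  and NIR, legumes greener and brighter in SWIR than corn) so that class
  separation comes mainly from the temporal profile, as intended.
* **Calendars.** 5-day cadence April–September. The 2019 calendar keeps the
  27 usable scenes (June and July each lose scenes to clouds, September all
  but 4 Sep); the 2020 calendar keeps a scene every ~15 days from 21 April,
  which makes C4 the only feasible combination on 6 May and all four
  feasible by 20 June. Cloudy dates are whole-scene losses.

**What the generator does not emulate** — and hence what passing tests do
not show about field data: radiative transfer and atmosphere residuals,
within-plot heterogeneity and mixed pixels at parcel borders, correlated
(non-iid) noise, weather-driven phenology variation between plots of the
same crop, partial cloud and cloud shadow, and registration error. Synthetic
class separation is consequently cleaner than reality: transfer accuracies
on the synthetic cycle pair sit in the mid-90s where field results top out
in the high 80s. The pipeline's *qualitative* behaviours — accuracy rising
through the season, short-lag pairs usable earliest, the bean class weakest
— are the transferable conclusions.

## Numerical and design choices

* Reflectance clipped to [0, 1] after noise; all dates ISO-8601
  `datetime.date`s; all randomness flows from one root seed split per stage
  (SHA-256 of `seed:stage`, 31-bit), so full runs are byte-reproducible.
* Constant descriptors standardise to zero with unit divisor (no 0/0).
* Degenerate inputs raise rather than return sentinels: empty sampling
  units, zero red-band sums, NDVI zero denominators, single-class training
  tables, record-length mismatches, kappa on single-cell matrices.
* The raster adapter works on in-memory numpy band stacks with a north-up
  affine origin/pixel-size and shapely polygons (pixel-center-in-polygon
  rule, matching CRS required); plot polygons round-trip through GeoJSON.
* Problem sizes used by the test suite and acceptance checks: the full
  280-plot survey and 895-plot test cycle, 10 seed pairs for the
  cross-cycle transfer check — one simulate→train→evaluate pass takes a few
  seconds on a single CPU, so the defaults are run unscaled.

## Known limitations

Bean recognition degrades after its early-July harvest by construction (the
records are filtered as non-standing), so late-season test sets contain
almost no bean — mirroring the operational reality. The one-vs-one SVM
stores one machine per class pair (fine for 3–4 classes, quadratic growth
beyond). The emergence filter's noise sensitivity near the 0.005 boundary
lets a small fraction of bare-scene records leak through at the default
noise level; this is realistic and handled by the classifiers, but noise-free
assertions in tests set `noise_sd=0`.
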