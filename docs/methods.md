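# Methods

This note documents the models implemented in `pamonitor`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## Study system emulated by the generator

The protocol targets a fire-prone Atlantic–Mediterranean transition
landscape monitored at two dates (2001 and 2014 in the package defaults):
a mosaic of native deciduous forest, pine plantations, closed and open
shrubland, meadow/fallow, arable land, water and urban patches, surveyed
for diurnal raptors by road transects on a coarse sampling lattice, and
overlaid by three protected-area systems — SACs (Habitats Directive),
SPAs (Birds Directive) and their union N2000. The generator reproduces
the *statistical structure* of those inputs:

- **Class maps.** Eight per-class Gaussian random fields (white noise
  smoothed with a Gaussian kernel whose sigma is the class's
  autocorrelation range divided by the cell size, wrap-around boundaries)
  are combined by weighted argmax. Per-class offsets are calibrated
  iteratively on the realized fields until class proportions match the
  configured weights to 0.2 percentage points, so proportions are
  reproducible by construction. Default weights (20/15/22/13/13/12/3/2%)
  describe a forest–shrubland mosaic with marginal agriculture; default
  autocorrelation ranges (200–400 m) give patch sizes of a few hundred
  meters.
- **Temporal change.** The second-date class map applies a Markov
  transition independently per cell. The default matrix encodes fire
  (closed → open shrubland, 12%/yr-period), vegetation regrowth
  (open → closed, 25%), conifer clear-cutting and crop/fallow rotation;
  water and urban rows are the identity, reflecting their assumed
  constancy over the period.
- **Scenes.** Per-cell reflectance is drawn from the class's Gaussian
  spectral signature over six reflective bands (blue…SWIR2). Default
  means are plausible surface-reflectance magnitudes; the default
  standard deviation (0.01, diagonal covariance) makes every class pair
  separable (transformed divergence > 1.99), which is the regime the
  protocol requires of its training data.
- **Surveys.** Straight east–west transects in randomly sampled lattice
  cells, with candidate points every `point_spacing` meters (default
  500 m); a cell whose route length exceeds its width receives several
  passes. Each species' presence at a point is Bernoulli with
  logit p = intercept + Σ_c coeff_c · (% class c within its radius).
  The seven default species span an open-habitat specialist (CPYG,
  closed shrubland at 500 m) to forest species at 1–2 km radii, with
  intercepts placing expected yearly presence counts in the tens to low
  hundreds.
- **PA masks.** SAC and SPA are grown cell-by-cell from random seeds
  (random frontier annexation, 4-neighborhood), first growing the SPA
  inside the SAC until the requested overlap is reached and then outside
  it, so realized coverages match the requested fractions to cell
  rounding. Defaults (16.6% SAC, 8.3% SPA, 7% overlap → 17.9% N2000)
  describe strongly overlapping systems.

**What the generator does not emulate** — and hence what green tests do
*not* demonstrate about real data: atmospheric/topographic effects,
phenology and seasonal compositing, mixed pixels and class gradients
(each cell is pure), spatially varying detectability of observers, roads
(transects stand in for them), and non-stationary species–habitat
relationships. Classification accuracy on synthetic scenes is therefore
near 1.0, well above what real scenes allow.

## Land-cover classification

Per-pixel Gaussian classifiers over class signatures estimated from
training cells (sample mean and covariance; at least B+1 cells per class
are required and singular covariances raise a typed error naming the
class). Priors default to equal rather than training-area proportions
because digitized training polygons are not an area-proportional sample.
NDVI is available as an appended ancillary band rather than a separate
stage. Ties in argmax/argmin break toward the lowest class id, making
outputs order-deterministic; under shared covariance and equal priors the
maximum-likelihood and Mahalanobis rules coincide cell-exactly (tested).
The artificial-neural-network classifier of the original protocol is out
of scope; the method enum is extensible.

## Multi-scale predictors

Composition is a count of cell centers inside the disc (center-in-disc
rule — unambiguous and consistent with count-based area estimation).
Point tables use exact discs centered on the point; projection stacks
evaluate discs centered on analysis-cell centers (500-m grain by
default; the grain must be an integer multiple of the source cell size).
Windows truncated by the map edge are renormalized over the available
cells and flagged incomplete; the table carries raw percentages (water
and urban are computed internally but excluded from predictor columns,
matching the six-class covariate schema). Coordinates are map meters,
x east / y north, rasters row-major from the north-west corner.

## Suitability modelling

- **Backgrounds.** Target-group backgrounds are the presence points of
  the other species in the same year's survey, deduplicated by exact
  coordinate equality (survey points are discrete route stops) and
  excluding locations where the target is present. Species-years with
  ≤ `min_presences` (default 10) presences are rejected with a typed
  error; a `pooled` flag moves the filter to the pooled two-year count
  (the per-year reading is the default).
- **Splits.** Stratified 70/30 splits, 30 replicates, seeded.
- **Learners.** A registry; shipped references are a standardized
  penalized logistic scorer and a surface range envelope (per-predictor
  percentile box on calibration presences, default 2.5–97.5). The
  original ten-algorithm roster is replaced by this contract — the
  protocol, not the learners, is the contribution — and additional
  learners (e.g. tree ensembles from scikit-learn) can be registered.
- **Evaluation.** AUC by rank statistic; TSS and κ maximized over a
  fixed 0.00–1.00 threshold grid in steps of 0.01 (the peak threshold is
  recorded).
- **Ensemble.** Cell-wise weighted mean with weights ∝ max(TSS, 0)
  among members at or above a quality floor (default TSS ≥ 0.4,
  configurable to 0; the pipeline retries a failed floor at 0 with a
  logged note rather than dropping the species-year). Members whose
  calibration subset degenerates to one class are excluded and logged.
- **Boyce index.** 101 windows of width 0.1 × the landscape suitability
  range; P/E per window; windows with zero expected frequency dropped;
  Spearman correlation of window mid-suitability against P/E. Constant
  landscapes or constant P/E return a typed "undefined" result, never a
  silent 0. The estimator is exactly invariant to affine rescaling of
  predictions and invariant to monotone transforms up to window
  re-binning.
- **Radius selection.** Per species, the radius whose projected ensemble
  maximizes the Boyce score (averaged over the two dates in the
  pipeline); ties go to the smaller radius. The 5-km level is excluded
  from the default candidate set, mirroring its exclusion from the
  assessment after poor performance.

## Habitat layers and indices

SH uses the 10th percentile (linear interpolation) of suitability at the
species' presence records — the percentile-training-presence convention,
chosen because the omission-error rationale for the threshold is defined
relative to presences, not to the whole-map distribution (a map-quantile
alternative is exposed in config). "Above" is implemented as ≥ so
constant maps do not produce empty masks. HSH is SH cells at or above
the mean suitability within SH; HSH ⊆ SH by construction.

Effectiveness and efficiency clip the habitat numerator to the system
mask (`clip_to_system` semantics): efficiency reads as protection per
unit protected area only when the habitat counted lies inside the
system, and this keeps efficiency ≤ 100%. Indices are reported on the
0–100% scale; the efficiency reciprocal (hectares protected per hectare
of habitat) is reported alongside. Threat weights are
T = (2 if Annex I else 1) × (2 if SPEC-listed else 1); SPEC levels other
than SPEC3 also weigh 2 (the formula only distinguishes listed vs not)
with a warning. Species with undefined indices (zero baselines) are
dropped from the corresponding weighted aggregate with an explicit note,
never imputed. Because representativeness and efficiency exist per date
while the published summary prints one value per index and system, the
weighted aggregates average the two dates for those two indices;
effectiveness is inherently two-date.

## Reproducibility conventions

Every generator and the full pipeline are pure functions of
(configuration, seed); `run_all` spawns per-stage seeds from the master
seed in a fixed order and serializes the report deterministically
(sorted keys, 6-decimal rounding), so identical inputs give
byte-identical reports. Problem sizes used by the test suite and the
acceptance script — a 10 × 10 km default region (200 × 200 cells of
50 m; 400 analysis cells at the 500-m grain), 120 × 120 cells for the
pipeline invariance tests, 20 × 20 km for the recovery experiment — were
chosen so that each stage keeps the statistical structure of the full
protocol while a complete run stays in the tens of seconds.

## Self-validation and a known limitation of radius selection

`experiments.radius_recovery_trial` closes the loop on the generator:
occurrences are simulated for a sharply separated narrow specialist
(logistic slope 0.3 per percentage point of closed-shrubland cover,
midpoint at 40% cover, true radius 1 km, ~300+ presences from a survey
lattice spanning the whole region), models are built blind at 500 m,
1 km and 2 km, and the Boyce-selected radius and the Jaccard overlap of
the recovered HSH with the true top-decile suitability region are
recorded. The sharp niche is deliberate: with a shallow response the
true suitability field is smooth and its top decile is an arbitrary
slice, so even a perfect model's HSH cannot match it (oracle Jaccard
≈ 0.32, versus ≈ 0.9 for the sharp niche).

The experiment exposes a real limitation: **the continuous Boyce index
has little power to identify the habitat-characterization radius in
this generative family.** Any model refit at any radius is
(asymptotically) monotone-calibrated on its own score, and the Boyce
index is insensitive to monotone recalibration, so its expectation is
near 1 at *every* radius; finite-sample window-occupancy noise then
decides the selection and systematically favors smoother, coarser-radius
projections for sharp-niche species. Member AUC, by contrast, identifies
the generative radius in essentially every replicate (the acceptance
script reports both rates). In the source protocol the decisiveness of
the Boyce score plausibly rests on overfitting behavior of flexible
learners and real-world non-monotonicities that a linear-logistic
generator cannot produce. The package implements the protocol as
specified and reports the recovery rates honestly rather than switching
the selector to AUC.
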