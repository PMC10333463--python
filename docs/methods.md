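# Methods

## The problem and the model

A regional forest-carbon assessment has three unsatisfying data sources:
process-based land models that disagree on absolute carbon density by tens
of Mg C/ha, a greenness index (NDVI) that tracks vegetation but not carbon
directly, and field plots that are accurate but sparse and tied to a single
campaign window. The package treats the models as *features*, not as
estimates: a random-forest regressor (the multi-model random-forest
ensemble, MMRFE) learns the mapping from the K model values at a pixel —
plus fused NDVI in the historical era — to observed plot density, then
applies it to every pixel and year. The natural baseline is the multi-model
ensemble mean (MMEM), the per-pixel average of the raw models.

Four regressor objects exist in a full analysis: {cVeg, cSoil} ×
{historical, future}. The future era trains without NDVI because no future
NDVI exists; the pipeline enforces this. At prediction time the historical
models receive the prediction year's fused NDVI (not a climatology): the
year-specific value is the only NDVI that varies with the quantity being
predicted, and using it keeps training and prediction features on the same
footing.

Total ecosystem carbon density is cVeg + cSoil; stocks are area integrals
over spherical-Earth cell areas `R²·Δλ·(sin φ_top − sin φ_bottom)` with
R = 6 371 km.

## NDVI fusion

The fusion chain is MVC compositing (per-pixel maximum of the biweekly
layers of a month), an annual mean over months with NDVI > 0.1, per-sensor
climatologies over the common overlap window, bilinear resampling of the
coarse annual grid to the fine geometry, and the ratio correction

    fused = (1 + (NDVI_G − ANDVI_M)/ANDVI_M) · NDVI_G / V,  V = ANDVI_G/ANDVI_M.

Choices worth stating:

- **Climatology window.** Both climatologies are taken over the same
  configurable sensor-overlap window. Comparability requires a shared
  window; a per-sensor window would fold sensor-era differences into the
  correction factor.
- **Annual-mean divisor.** The annual mean divides by the *count of
  qualifying months*, not a fixed 12. A fixed divisor would bias vegetated
  pixels with short growing seasons toward zero and make the vegetation
  threshold a magnitude distortion instead of a mask.
- **The cancellation.** Algebraically the expression reduces to
  NDVI_G²/ANDVI_G: the fine sensor's climatology cancels and affects the
  output only through masking. Both the literal composition and the
  simplified form are implemented, and their equality is asserted in tests
  (≤ 1e−12 relative). Users who want the fine sensor to shape the output
  radiometrically should treat this as a property of the formula, not of
  the implementation.
- **Edges and gaps.** Resampling clamps to the outermost source centers
  (no extrapolation); missing bilinear neighbors renormalize the remaining
  weights; pixels with non-positive climatology are masked and counted in
  the log. Output is clipped to the physical NDVI range [−0.2, 1].

## Training the ensemble

Plots are associated to their containing pixel (half-open cells
[west, east) × (south, north], row 0 northernmost); rows with any missing
feature are dropped and counted. Training uses a 75 % train / 25 % holdout
split — the alternative reading, a bootstrap resample as the training set,
is available via `MMRFEConfig(bootstrap_split=True)` — with a small
cross-validated grid search (features per split 0.33/1.0, minimum leaf
1/4, 200 trees, 3 folds). Forests at plot-scale sample sizes are
insensitive to finer tuning, and a small declared grid keeps runs fast and
reproducible. Holdout correlation and RMSE are recorded on the fitted
object; predictions clip at zero (carbon density is nonnegative) and
propagate input masks. Features are keyed by model *name*, so permuting a
stack cannot silently misalign columns; a missing or extra feature at
prediction time is a hard error.

## Validation statistics

Taylor statistics use population (1/N) normalizers throughout. The RMSD is
the standard *centered* pattern RMS difference,
√(1/N Σ[(m−m̄)−(o−ō)]²), which satisfies the law-of-cosines identity
RMSD² = σ_m² + σ_o² − 2σ_mσ_oR; every computed row is required to satisfy
it to 1e−10 relative. (An alternative reading that squares the *product*
of anomalies would be a fourth-moment quantity incompatible with the
Taylor framework; it is not shipped.) All statistics use pairwise-complete
samples; zero-variance inputs raise instead of returning NaN.

## Accounting

Annual stock series are summarized in 5-year spans: mean, SD of the annual
stocks within the span, increment over the previous span, cumulative
increment over a baseline, and the CO₂ equivalent of the cumulative
increment. The baseline is the first span's mean for historical tables and
the historical-period mean stock for scenario tables. Increments telescope
exactly: their sum equals the final cumulative increment.

The CO₂ factor defaults to 36.67 Bt CO₂ per Pg C. This is ten times the
molar ratio 44/12 = 3.667; the default reproduces the source convention
the accounting tables follow, and the factor is an explicit argument
everywhere so the molar value is one keyword away. Trend maps are
closed-form per-pixel OLS slopes with per-pixel valid-year counts; pixels
with fewer than 3 valid years are masked.

## Carbon-sink index and zoning

CSindex is the percentage of strictly positive year-to-year increments
over an N-step window (N = 39 for a 40-year record); a zero increment
counts as a non-sink year. It depends only on increment *signs*, so it is
invariant to adding a constant or to positive-slope affine rescaling —
both properties are tested. Pixels with intermittent masks use their valid
consecutive pairs only.

Zoning runs 1-D K-means (k-means++ init, 10 restarts, fixed seed) on the
index values and relabels clusters by ascending centroid into weak /
medium / strong. Reported alongside the labels: centroids, midpoints
between adjacent centroids, and the empirical min/max of each cluster —
the lower edge of a class is the operative threshold between it and the
class below. K-means on well-separated modes is initialization-stable;
on a unimodal index map the boundaries should be read as a ranking device,
not as physically meaningful breaks.

## The synthetic generator

The generator emulates the *structure* the analysis assumes, not any real
geography:

- **Truth**: per variable, a fixed spatial base pattern (Gaussian-kernel
  smoothed white noise, correlation length = kernel σ in cells, default 3)
  plus a linear trend (default 0.07 Mg C/ha/yr) plus spatially correlated
  interannual noise (default SD 1 Mg C/ha), clipped at zero; defaults
  mean 43 Mg C/ha (cVeg) and 147 Mg C/ha (cSoil) with spatial SDs 15/40.
  A smooth-field quantile threshold carves out 10 % of the domain as
  non-forest, giving every stage a mask to propagate.
- **Model ensemble**: model_k = a_k·truth + b_k + correlated noise(sd_k),
  defaults a ∈ [0.7, 1.3], b ∈ [−30, 30] Mg C/ha, sd ∈ [10, 40] Mg C/ha
  across seven models — a spread of the magnitude process-model
  intercomparisons show.
- **NDVI**: v_max·c/(c+h) with v_max = 0.9 and h defaulting to the mean
  cVeg (so synthetic NDVI spans the responsive mid-range of the
  saturation curve), plus an additive seasonal cycle over 24 biweekly
  layers and sensor noise, clipped to [−0.2, 1]; the coarse sensor is the
  block mean of the fine cube plus its own noise.
- **Plots**: uniform random sample of unmasked pixel centers, observed
  value = truth + Normal(0, 5 Mg C/ha). Real campaigns stratify by forest
  type and interpolate plot values to a surface; neither is emulated, so
  passing tests demonstrate the machinery, not robustness to survey
  design. The reference year defaults to the midpoint of the historical
  range (the campaign-anchor year).

All randomness flows from explicit seeds through `SeedSequence.spawn`, so
identical configs give bit-identical outputs — the end-to-end manifest
digest depends on this.

What the generator does *not* emulate: real land-cover geography,
non-linear model biases, spatially varying observation error, NDVI
saturation regimes differing by biome, and sensor orbit/compositing
artifacts. Synthetic results quantify method behavior under the stated
assumptions; they do not predict real-data skill.

## Problem sizes and numerical choices

The default pipeline runs on a 32×32 grid, 40 historical plus 60 scenario
years, 7 models and 300 plots — large enough that span tables have 8 and
12 rows and zoning has thousands of index values, small enough for
interactive rerunning. The recovery experiment uses the 48×48 / 500-plot
/ 10-seed configuration described in the README. Tolerances: exact
identities are asserted at 1e−12 relative (fusion algebra, telescoping),
the Taylor identity at 1e−10, conservation of zonal aggregation at 1e−9,
and stochastic recovery criteria by majority over seeds (≥ 8 of 10).

## Known limitations

- A random forest cannot extrapolate beyond the target range seen in
  training. Scenario predictions late in the century, when model features
  drift past their reference-year range, saturate toward the trained
  maximum; scenario contrasts then compress (the high-forcing scenario can
  even fall below the moderate one in cumulative terms). This is inherent
  to tree ensembles used as emulators, and is the main caution when
  reading the future-period tables.
- The fusion formula's fine-sensor cancellation (above) means the fine
  record cannot correct coarse-era radiometry; it only masks.
- K-means zone boundaries on a continuous unimodal index are a convenient
  discretization, not detected regime breaks.
- The per-span SD is the SD of annual stocks within the span; it measures
  interannual variability, not ensemble or parameter uncertainty.
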