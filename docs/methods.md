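# Methods

## Data model and reference-frame normalization

A compilation record is one isotope measurement of one tissue (hair, nail,
bone, tooth enamel) with WGS84 origin coordinates, origin status (known =
residence during tissue growth documented by the donor; assumed = inferred,
e.g. from the collection location), study identifier, and — for teeth — a
crown-formation age group. All oxygen values are normalized at load time to
one currency, VSMOW scale and carbonate-equivalent phase, using two fixed
linear conversions:

* VPDB → VSMOW: `δ¹⁸O_VSMOW = 1.03092·δ¹⁸O_VPDB + 30.92`
* phosphate → carbonate: `δ¹⁸O_C = (δ¹⁸O_P + 9.6849)/1.0322`

Scale and phase must be declared as columns; nothing is inferred from value
magnitude, because a silently misclassified scale is far worse than a load
error. Validation bounds: ⁸⁷Sr/⁸⁶Sr ∈ (0.70, 0.75), δ¹⁸O (VSMOW) ∈ (−30,
+40) ‰. Invalid rows are dropped with row-level diagnostics, never fatal.

Tooth elements map onto four crown-formation windows — 0–4 y (first molars,
central incisors), 0.5–6 y (lateral incisors, canines), 2.5–7 y (premolars,
second molars), 7.5–15 y (third molars) — with an Unknown group for labels
(bare "molar", "incisor") that span more than one window. Records whose
listed residence locations are more than 25 km apart (midpoint of the usual
20–30 km proximity window) can be dropped with `filter_multiple_origins`.
Ages ≥ 18 y are binned as adult. Sample ids get an analysis-type suffix
(-O/-Sr) so repeat analyses of one physical sample stay unique.

Keratin δ¹⁸O data calibrated against different in-house reference materials
are mapped onto a common VSMOW realization through per-scale linear
(gain, offset) coefficients supplied as configuration (`ScaleTransform`).
No coefficients are invented: an unknown scale label raises, mirroring the
practice of excluding samples whose calibration scale cannot be determined.

## Tap-water isoscape by difference kriging

The tap-water surface is `T(x) = P(x) + OK[tᵢ − P(xᵢ)](x)`: station values
are differenced against the base precipitation raster at their cells, the
difference field is interpolated by ordinary kriging, and the interpolated
differences are added back. Kriging the difference (rather than the raw tap
values) preserves the base surface's structure between stations and makes
the construction exact in two limits: where tap equals precipitation the
output is the base surface, and at a station's cell with a zero-nugget model
the output equals the station's value.

Numerical choices:

* Semivariogram: exponential family by default (spherical and gaussian
  available), fitted by weighted least squares to a 15-bin empirical
  variogram with weights `n_pairs/h²` and a cutoff of half the maximum
  pairwise distance — gstat-like conventions. Optimizer failure falls back
  to a pure-nugget model with a logged warning.
* Distances are great-circle km (haversine, WGS84 mean radius); the kriging
  system treats them as planar. At continental scale the resulting
  covariance matrices remain valid for these families in practice; this is
  a documented approximation, not an exact spherical model.
* The ordinary-kriging system is solved in covariance form with the
  unbiasedness constraint (weights sum to 1, asserted in tests via the
  constant-shift property). Duplicate stations are averaged first.
  With ≤ 64 observations one global system is factorized and reused for all
  cells; above that each cell uses its 64 nearest stations.
* Grid and resolution are inherited from the base raster; no resampling.
  Cells are half-open; point extraction returns the containing cell's value
  (no bilinear interpolation), matching common GIS raster-extraction
  semantics. Rasters are stored as ESRI ASCII grids — a text format chosen
  deliberately so the whole toolchain is reproducible without binary I/O
  dependencies; nodata is NaN in memory and excluded from every statistic.

## Calibration

`calibrate` minimizes `Σ wᵢ(yᵢ − α − β·eᵢ)²` in closed form. The default
weighting is site-frequency (`wᵢ = 1/nₛᵢₜₑ`), so a transect of 100 samples
from one city counts like one well-characterized site; unit weights (plain
OLS) are one switch away, and both are first-class because published fits of
this kind rarely state their weights. R² is the weighted `1 − SSE/SST`, RSE
is `√(SSE_w/(n−2))`. Records on nodata cells are excluded and counted,
never imputed.

The OLS slope of tissue on environment is attenuated by error in the
environmental predictor; the reduced-major-axis slope
(`sd(y)/sd(e)`, signed by the correlation) is provided for the symmetric
error case, where it is the appropriate summary of proportional variation.

The tissue isoscape is `μ(x) = α + β·e(x)` with a spatially constant
prediction sd equal to the RSE. Per-cell environmental prediction
uncertainty is not folded in (no defensible combination rule without a
variance raster for the base surface); the sd is floored at 1e-9 so the
assignment posterior stays defined in the noiseless limit.

## Residual diagnostics and bias correction

Three hypotheses about the compilation map onto two tests over calibration
residuals:

1. Assumed-origin samples degrade the tissue–environment relation → wider
   residual dispersion for the assumed group (Levene's test; Brown–Forsythe
   median centering by default, as the robust common default — mean
   centering is a config option).
2. Laboratory/method differences between studies → offset per-study mean
   residuals (one-way fixed-effects ANOVA).
3. Tooth mineralization age affects body-water δ¹⁸O → offset mean residuals
   across tooth groups (ANOVA; the heterogeneous Unknown group is kept in
   summaries but excluded from the ANOVA by default).

p-values are reported, never auto-thresholded; 0.05 appears only as an
annotation. Degenerate inputs have defined outcomes: zero within-group
variance with unequal means reports F = +∞ with p = 0; all-zero spreads in
the variance test raise.

Bias correction subtracts each group's mean residual from its published
values. Only offset *contrasts* are identifiable — the fitted intercept
absorbs the record-weighted mean offset — so corrections are centered:
recomputing residuals under the same fit gives per-group means of exactly
zero, while a refit leaves group means near (not at) zero because group
indicators are not orthogonal to the regressors. Corrections are estimated
and applied on the same dataset by default (matching standard practice for
this correction); a leave-group-out mode exists for honesty checks. The
Unknown tooth group is left uncorrected by default.

## Assignment and quality assessment

The posterior surface for an observed value `y` is the normal density
`N(y; μ(x), σ(x))` per cell, computed in log space and normalized by the
area-weighted sum; cell-area weights are normalized cos(latitude) of the
cell center, because lon/lat grids are not equal-area and assignment
regions are area statements. Assignment regions take cells in decreasing
posterior-density order (ties broken by row-major index, deterministically)
until the cumulative area weight reaches the target fraction `q`.

QA repeats, `n_iterations` times (default 10): split the dataset at random
(record-level by default; site-level splitting available to probe spatial
leakage; validation fraction 0.25), calibrate on the retained part, predict
the tissue isoscape, and for each held-out sample record the smallest `q`
whose region contains the cell of its reported origin ("correct" is cell
membership, not a distance buffer). Accuracy(q), averaged over samples and
iterations, is nondecreasing with accuracy(1) = 1; data carrying no
geographic signal give accuracy(q) ≈ q (the random-assignment diagonal).
The q grid defaults to 0.01…1.00 in steps of 0.01. Everything is driven by
one integer seed and is exactly reproducible.

## Synthetic worlds

The generator states a world and the pipeline is tested against it:

* Environmental raster: a seeded superposition of 12 low-frequency cosine
  plane waves rescaled to a target range. This replaces a Gaussian-process
  simulator (no heavy dependency, exact determinism); the claimed spatial
  autocorrelation is verified by a lag-correlation test, not assumed.
* Tap stations: base value + one smooth long-wavelength offset field +
  station noise (sd 0.2‰), emulating tap water's regional departure from
  precipitation.
* Tissue records: `y = α + β·e(site) + study bias + tooth offset +
  N(0, σ)`, sites uniform over valid cells. A seeded fraction of records is
  flagged assumed-origin and has its *recorded* coordinate displaced from
  the true growth site by an exponential-distance (scale `displacement_km`),
  uniform-direction kernel — enough to create origin error without modeling
  migration. A truth table accompanies every dataset.

Defaults are the conditions the recovery tests state: 100 sites × 5
records, noise 1‰, slope 0.35 (the theoretical fraction of drinking-water
variation expressed in hair keratin), study offsets {+1.5, 0, −0.5}‰,
assumed fraction 0.25, displacement scale 100 km. Named presets pin the
three fitted tissue–environment relations: hair δ¹⁸O (slope 0.35, RSE-like
noise 1.5‰), enamel δ¹⁸O (slope 0.43, noise 1.6‰, study and tooth-group
offsets spanning ~3‰), enamel ⁸⁷Sr/⁸⁶Sr (slope 0.53, noise 0.0014 — between
the observed per-group dispersions 0.0011 and 0.0016).

What a green test does and does not establish: the synthetic world has a
single isotropic autocorrelation scale, uniform site placement, balanced
study membership independent of geography, and exactly linear
tissue–environment coupling. Real compilations violate all four (patchy
sampling, studies confounded with region, nonlinear damping of high Sr
ratios), so recovery and QA results here validate the *machinery*, not the
field performance of any particular compilation.

## Reproducing published-compilation analyses

`tests/test_acceptance.py::test_deposited_data_reproduction` runs the full
reproduction (enamel-Sr and hair/enamel-O calibrations, RMA slope, residual
dispersions, corrected QA accuracy) when the deposited compilation CSV and
the two environmental isoscapes are placed under `data/deposited/` as
`compilation.csv`, `tapwater.asc` and `bioavailable_sr.asc` (convert
GeoTIFFs to ASCII grid with any GIS tool, e.g. `gdal_translate -of AAIGrid`).
These inputs are a multi-megabyte external download and are not bundled, so
the test reports failure in an offline checkout. Exact weighting and QA
settings behind the published numbers are not fully specified, so those
comparisons carry the tolerances stated in the test rather than printed
precision.

## Known limitations

* Kriging is isotropic and planar-in-distance; no regression kriging with
  covariates, no anisotropy.
* Tissue-isoscape sd ignores environmental-isoscape uncertainty (constant
  RSE), so posterior surfaces are overconfident where the base isoscape is
  poorly constrained.
* Single-analyte assignment only; no joint O×Sr posterior products.
* The compilation loader trusts supplied coordinates; no geocoding.
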