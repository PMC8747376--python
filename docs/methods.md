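# Methods

`maizephen` re-implements, as a tested library, a pipeline for recognising
maize phenological stages in 4-band (blue, green, red, NIR) satellite
composites: per-plot indicator extraction, assembly of a canonical
86-feature table, and supervised classification of six BBCH-derived stages
(emergence, development, tassels-and-ears, ear formation/maturation,
beginning of senescence, end of senescence). Because the original field
data are not publicly deposited, the package ships a synthetic scene
generator that reproduces the statistical structure the analysis assumes;
everything downstream of image acquisition is fully testable against it.

## Indicator channels

A plot sample is the set of masked pixels of one plot on one date.
Digital numbers are mapped to reflectance by `min(dn/scale, 1)` with
`scale = 10000` (the Sentinel-2 L2A convention); the colour transforms
require bounded input, which is why the normalisation is applied even
though the pipeline is otherwise agnostic to radiometric calibration.
Thirteen colour planes are computed per sample: reflectance R, G, B, NIR;
HSV (hexcone, H normalised to [0,1)); CIE 1976 L\*a\*b\* (sRGB
linearisation, D65 white — the convention of common engineering toolboxes;
delegated to scikit-image); and NTSC YIQ via the documented 3×3 matrix.
NIR participates only as a raw reflectance plane; it is not pushed through
the colour models.

**Local Moran's I (LISA).** For pixel *i*,
`I_i = (x_i − x̄)/s² · Σ_j w_ij (x_j − x̄)`, with the mean and *population*
variance (divide by *n*) taken over the masked pixels of the plot window —
not the whole scene; indicators are applied per extracted sample, and the
plot is the region of interest. Adjacency is queen contiguity restricted
to the mask; edge pixels keep their actual (< 8) neighbours. Four weight
schemes are implemented — row-standardised `W` (rows sum to 1, the
default), globally standardised `C` (total = n), uniform `U` (total = 1)
and binary `B` — with identities asserted in tests. Under `W` the mean of
the local values equals the global Moran's I (Anselin's decomposition),
which the suite checks against a brute-force oracle. A constant plane has
zero variance; the channel is then flagged and imputed 0. Constancy is
detected with an exact max-equals-min check because floating-point
summation can leave a ~1e-34 variance residue on constant input.

**LBP.** Code = `Σ_p s(g_p − g_c)·2^p` with `s(x) = 1` iff `x ≥ 0` — ties
set the bit, so a constant window codes 255 everywhere. `P = 8`; bit 0 is
the east neighbour and bits proceed counter-clockwise; the radius defaults
to 1 (the 8 adjacent pixels) and larger radii take the same 8 directions
at offset R without interpolation. Pixels lacking a complete masked
neighbourhood are excluded. These conventions are fixed so codes are
reproducible; rotation-invariant/uniform variants are out of scope.

**Vegetation.** `SAVI = (1+L)(NIR−RED)/(L+NIR+RED)` with soil factor
`L = 0.5`, and `LAI = −ln((0.69 − SAVI)/0.59)/0.91` for `SAVI < 0.69`.
At or beyond the 0.69 saturation point the logarithm is undefined; such
pixels are capped at a configurable `LAI = 6.0` (a typical closed-canopy
maximum) and flagged. Negative LAI (SAVI < 0.10) is kept by default to
preserve the printed formula; clipping is available. A soil-factor
narrative in the source material conflicts with the fixed `L = 0.5`; the
fixed value is used.

## Feature schemas

Each of the 43 channels (13 colour + 13 LISA + 13 LBP + 3 ratios + LAI)
contributes its mean and *sample* variance (n−1) over the masked pixels:
86 features, partitioned 26 colour / 52 texture / 8 vegetation. LISA uses
one configured weight scheme (default `W`) so the texture accounting
stays one channel per plane. The 45-feature "main characteristics"
schema reproduces the published selection exactly (11 LISA, 10 LBP,
8 RGB+NIR, 6 L\*a\*b\*, 2 Q-chroma, 6 ratios, 2 LAI), including its name
grammar (`lisa_rv`, `lmorl*_m`, `lbpq*_v`, `Ratio_gm`, …; one obvious
typographical variant was normalised to `Ratio_bv`). Six ablation subsets
drop one indicator group each (34/35/43/39/37/39 features). Degenerate
channels are imputed 0 and flagged so tables stay rectangular.

The published per-stage sample counts (715/1214/227/963/511/385, total
4015; and the five-stage 828/1085/903/520/428, total 3764) are shipped as
constants for bookkeeping. Dropping stage 3 removes exactly 227 rows
(leaving 3788); the further expert relabeling that produced the five-stage
3764 is not mechanically reproducible and is left to external relabel
tables.

Greedy selection starts from the six RGB colour features and visits the
remaining features once in canonical schema order, keeping a feature iff
the cross-validated overall precision does not decrease. The original
procedure was interactive trial and error in a GUI; fixing the visit order
and the fold split (one seed) makes the pass deterministic.

## Classifiers and evaluation

* **LDA** uses the closed-form estimators (priors `N_k/N`, class means,
  pooled covariance with the `N − K` denominator) and predicts by the
  linear discriminant score. A singular pooled covariance gets a ridge of
  `1e-6 · trace(Σ)/p` on the diagonal (with a 1e-6 floor when the trace is
  zero, e.g. one training point per class). Predictions are cross-checked
  against scikit-learn's implementation in the tests.
* **kNN**: majority vote among the k nearest (default k = 10, Euclidean;
  Manhattan/Minkowski selectable). Ties break by smallest aggregate
  distance, then lowest class label — deterministic by construction.
* **Quadratic SVM**: one-vs-one soft-margin SVMs with kernel
  `(γ⟨x_i,x_j⟩ + c)²`, γ = 1/p, c = 1, box constraint 1.0, features
  standardised — defaults mirroring common GUI tooling, all configurable.

The evaluation protocol resolves the source's conflation of a 90/10
holdout with 10-fold cross-validation by doing both: a stratified 90/10
split, stratified 10-fold CV on the 90 % (pooled out-of-fold confusion
matrix), and a final confusion matrix on the 10 %. Overall precision is
trace/total; per-class values are reported row-normalised (share of each
true stage classified correctly, the convention of the published
per-stage tables) *and* column-normalised (precision of the predictions),
because the printed per-class formula reads as the latter while the tables
use the former. All randomness descends from one seed recorded in every
report.

## Synthetic scenes

The generator emulates the monitored-plot layout: non-overlapping
rectangular plots on a bare-soil background, each carrying a per-stage
mean reflectance plus additive Gaussian noise that is spatially smoothed
(white noise convolved with an isotropic Gaussian kernel, re-normalised to
unit marginal standard deviation so `noise_sd` is the actual per-pixel
sd). Reflectance is clipped to [0,1], scaled by `dn_scale = 10000` and
rounded half-up to uint16 for platform-independent reproducibility; a
fixed seed yields bit-identical scenes.

Defaults mirror the study conditions: an 804 × 1498-pixel composite, 148
plots of 14 × 14 pixels (~2 ha at 10 m/pixel), six stages assigned
round-robin. No per-stage spectral statistics were published, so the
profiles are qualitative: greenness and NIR rise monotonically from
emergence to ear maturation and fall through senescence, red does the
opposite, and the SAVI of the profile means peaks at stage 4. The base
noise is `noise_sd = 0.015` reflectance with a 2-pixel autocorrelation
range. Both noise amplitude and autocorrelation are stage-dependent
(amplitude highest where soil and canopy mix — emergence and late
senescence — and lowest under closed canopy; spatial grain coarsening as
the canopy closes), which is what gives the texture indicators class
signal, as they have on real imagery. Amplitudes and ranges were chosen
once as plausible for L2A surface reflectance over maize and give a
feature-level Bayes error well under 2 %.

What the generator does *not* model: radiative transfer, sensor PSF and
resampling, cloud and shadow, mixed boundary pixels, irregular polygon
plots (supported by the extractor, not produced by the generator),
within-stage phenological drift between acquisition dates, and
between-plot agronomic variability. Passing the recovery tests therefore
shows the pipeline is correct and well-conditioned, not that the published
real-data accuracies (which are far lower) are reproducible; those depend
on undeposited field data and are excluded as numeric targets.

## Problem sizes and numerical choices

Experiments pool several generated dates: the recovery check uses 3 scenes
(444 samples) and the noise-degradation curve 20 replicate seeds at four
noise levels (0.015, 0.06, 0.15, 0.4) with one scene each — sizes chosen
to keep variance of the seed-averaged accuracies small. The degradation
assertion allows a fixed 0.01 slack on adjacent seed-averaged means as
sampling tolerance. Oracle comparisons (naive O(n²) local Moran, pixel-loop
LBP) run at 1e-10 absolute tolerance on random 6×6–8×8 masks. Chroma
checks on grey images use 0.01 tolerance because the sRGB/XYZ matrices are
rounded constants. Isolated pixels (no masked neighbour) get zero weight
rows and are flagged rather than erroring.

## Known limitations

GeoTIFF I/O is plain multiband uint16 TIFF; georeferencing beyond an
optional affine tuple is out of scope. Only the paper-facing LBP variant
is implemented (no uniform/rotation-invariant codes). kNN is deliberately
left unstandardised (its published description says nothing about
scaling), so its accuracy on the 86-feature table is dominated by the
large-scale LBP features — visible in the examples, and itself a faithful
illustration of why the quadratic SVM with standardisation wins.
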