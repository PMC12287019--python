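# Methods

This note documents the models, parameters and numerical choices behind
`vertfract`, and what validation on the synthetic phantom does and does not
establish about clinical data.

## The phantom

`vertfract.phantom` renders a mid-sagittal lumbar spine as a vertical stack
of bright rounded rectangles (vertebral bodies, VBs) on a dark background.
Defaults: 256×256 image, five VBs of 28×44 px with a 10 px intervertebral
gap and 4 px corner radius, foreground mean 170, background mean 40 (8-bit
gray levels). The geometry is a desk-scale choice — clinical sagittal MR
comes with arbitrary fields of view, so no single resolution is "correct" —
and the stack is centered with a guaranteed ≥4 px margin to every image
border so that border clearing during segmentation can never delete a true
vertebra.

**Fracture model.** A fractured VB is an anterior wedge compression: the
per-column height of the template is scaled linearly from
`1 − height_loss_fraction` at the anterior (left) edge to 1 at the
posterior edge, removing pixels from the superior endplate while keeping
the inferior endplate fixed; a smoothed Gaussian jitter
(`boundary_irregularity`, default 1 px standard deviation) perturbs the
superior boundary. Height loss defaults to 0.4 — a moderate-to-severe
wedge, the regime the classification stage is meant to detect. This is the
deformity that drives the shape features: the wedge lowers eccentricity
(λ₂/λ₁ drops from ≈0.40 to ≈0.28 at the default geometry) and
rectangularity (≈0.99 → ≈0.84).

**Intensity model.** A multiplicative bias field — the sum of two
low-frequency separable cosines with random phases, normalized into
`[1−bias_amplitude, 1+bias_amplitude]` (default amplitude 0.1) — emulates
coil inhomogeneity; i.i.d. Gaussian noise (default σ=5) is added and the
result is clipped to [0,255]. Deliberately *not* modeled: Rician noise
statistics, partial-volume effects, pulse-sequence contrast, posterior
elements, discs and soft tissue, and the benign/malignant distinction
within fractures. Consequently, passing end-to-end tests shows the pipeline
is internally consistent and recovers known geometry under noise and bias —
it does not certify clinical performance, where neighboring structures and
subtler fractures make both segmentation and classification genuinely
harder.

Cohorts are generated with per-vertebra i.i.d. Bernoulli fracture labels
(default prevalence 0.3, matching the roughly 30 % fractured fraction of
the clinical motivation); the default cohort of 63 cases × 5 VBs = 315
vertebrae mirrors the scale of the clinical benchmark the statistical
machinery is compared against. A single master seed fans out to every stage
(`stage_seed = master·1000003 + crc32(stage) mod 2³¹−1`), so identical
configurations reproduce identical bytes.

## Preprocessing

Spatial filtering is a neighborhood operator (median or mean, odd window,
reflect padding; default 3×3 median). Histogram equalization is the exact
global CDF construction with round-half-up, making the mapping
deterministic at .5 boundaries; the full `HistogramMap` (counts, CDF,
normalized CDF, level mapping) is returned for logging. Smoothing runs
before equalization so isolated noise spikes cannot distort the CDF. A
tiled-adaptive variant was considered and rejected: the global mapping is
the form that is exactly testable, and the phantom's bias amplitudes do not
require local adaptation.

**Order of equalization and thresholding.** The pipeline driver binarizes
the *smoothed, pre-equalization* image and uses the equalized image only
for intensity features. Rationale: global equalization maps quantiles onto
gray levels, so on an image that is mostly background the equalized
histogram is near-uniform and Otsu's between-class-variance criterion
mid-splits the background (measured on the default phantom: Otsu threshold
122 on the equalized image versus a true class boundary at ≈233, against
threshold 59 — correct — on the smoothed image). `segment.binarize` itself
is agnostic: it applies Otsu (or a fixed threshold) to whatever image it
receives.

## Segmentation

Binary morphology uses the standard set definitions — dilation keeps every
translation whose reflected structuring element hits the foreground,
erosion keeps translations where the element fits inside it (out-of-image
pixels count as background). The printed source inspiration for erosion
contains a typographical inversion (it describes the *complement* of the
fit condition); the standard operation is implemented. Closing (dilate then
erode, disk of radius 2) pads by the element radius first so the operation
keeps its infinite-plane properties (extensive, idempotent) on a finite
frame. Foreground components are 8-connected, holes 4-connected.

After closing, hole filling and border clearing, two filters remove
non-vertebral components: islands smaller than 5 % of the largest
component, and components whose centroid-x lies more than 0.15 × image
width from the median centroid-x (the spine is a roughly vertical column,
so VB centroids share an x-band; both thresholds are relative and therefore
FOV-invariant — the source material never quantifies them). Each surviving
component is replaced by the filled convex hull of its pixel centers, which
regularizes the boundary of compressed VBs; degenerate components (<3
pixels or collinear) are their own hull. Components are labeled L1…L5 by
centroid row, top down; a mismatch with the expected count raises a warning
flag rather than an error.

Contours are traced at the 0.5 iso-level of the padded mask (marching
squares), oriented clockwise in image coordinates starting from the
topmost-then-leftmost vertex. Sub-pixel iso-level vertices give stable
perimeter and curvature estimates on rasterized shapes, at the cost of the
contour being a polygon rather than a pixel chain.

## Shape features

All region statistics are computed over foreground *pixel centers*; all
contour statistics over the traced polygon.

- **Centroid, covariance, eccentricity.** Closed-form 2×2 eigenvalues;
  `E = λ₂/λ₁ ∈ (0,1]` (1 = isotropic; note this is the eigenvalue-ratio
  convention, not conic eccentricity). The axis of least inertia is the
  λ₁-eigenvector direction in [0, π); for isotropic shapes the angle is
  reported as 0 since orientation is undefined.
- **Bending energy.** The contour is resampled to 128 equal-arc-length
  points; derivatives come from the coordinate functions' Fourier series
  truncated at 8 harmonics, and BE is the mean squared curvature. For a
  circle of radius r this converges to 1/r². The cutoff of 8 is the key
  numerical choice: rasterized boundaries inject broadband staircase noise
  whose curvature contribution grows quadratically with harmonic index
  (at 16 harmonics the BE of a 14×8 px ellipse is 8× its analytic value;
  at 8 harmonics it is within ~8 %, and within ~2 % for 20 px shapes),
  while desk-scale vertebral outlines are fully described by the first few
  harmonics. Both knobs are configurable.
- **Rectangularity.** Pixel area over the area of the minimum-*area*
  bounding rectangle (rotating calipers on the contour's convex hull, via
  shapely), chosen over the axis-aligned box so the measure is
  orientation-free.
- **Convexity.** Hull perimeter / contour perimeter ≤ 1.
- **Euler number.** 8-connected components minus 4-connected holes
  (always 1 for a healthy segmented VB; deviations flag segmentation
  artifacts).
- **Profiles.** Column/row pixel counts over the bounding box. Raw
  profiles are variable-length, so the classifier vector carries four
  fixed summaries per axis: length, maximum, mean, and coefficient of
  variation. Length and mean respond directly to wedge height loss.
- **Intensity block.** In-mask mean, SD, skewness, kurtosis of the
  equalized image.

The resulting 17-element vector order is frozen in
`features.FEATURE_NAMES`. Centroid and inertia-axis angle are reported in
`ShapeFeatures` but excluded from the classifier vector: they encode
position and orientation, which carry no fracture information and would
break translation/rotation robustness.

## Balancing

SMOTE follows the classical algorithm exactly: a synthetic minority sample
is `x + u (x_n − x)` with `u ~ U(0,1)` and `x_n` one of the k = 5 nearest
minority neighbors (Euclidean). Original rows are never altered; synthetic
rows carry a `synthetic` provenance flag. Balancing is applied *inside*
each training split, after the split is fixed — balancing before splitting
would leak interpolated copies of test-adjacent samples into training and
inflate test metrics. Rotation augmentation (±15°, bilinear for images,
nearest for masks) is provided for image-space pipelines and validated for
area preservation and near-invertibility.

## Classification

Features are z-scored with training-split statistics only (both classifiers
are scale-sensitive). KNN is an exact brute-force implementation — distance
ties break to the lower training-row index, making predictions fully
deterministic; posteriors are neighbor class fractions. The SVM is the
standard linear soft-margin primal `½‖w‖² + C Σ hinge`, solved through the
dual (libsvm SMO via scikit-learn) with tol 10⁻⁶; the model records the
primal objective so independent convex solvers can verify it (tests check
agreement to 10⁻³ relative). Predictions are `sign(w·x+b)` with 0 mapped to
the positive (fractured) class. C is selected from {0.01, 0.1, 1, 10, 100}
by stratified 5-fold CV inside the training split. The grid-search driver
evaluates every (classifier, hyperparameter, split fraction) cell on
seeded stratified splits — stratification keeps both classes present at
the extreme 80:20 and 30:70 fractions on a 30 %-prevalence cohort — and
appends an Average row per arm (arithmetic mean over split fractions).
Splits are per-vertebra; a per-case grouping would be stricter about
patient-level leakage but the phantom's vertebrae are conditionally
independent given the spec, so per-vertebra splitting loses nothing here.

## Evaluation and statistics

Segmentation metrics (accuracy, sensitivity, Dice, Jaccard) and
classification metrics (accuracy, precision, recall, F1) are reported in
percent; zero-denominator cases return 0 with a `degenerate` flag instead
of raising, so batch evaluation survives empty predictions.
Leave-eleven-out cross-validation partitions cases *sequentially* into
disjoint test folds of 11 with a smaller final fold (63 → 11,11,11,11,11,8);
per-fold and per-level (L1–L5) metrics aggregate confusion counts before
computing ratios.

The paired t-test is the textbook statistic with n−1 degrees of freedom
(via scipy). The Wilcoxon signed-rank test is *exact*: zero differences are
dropped, tied absolute differences get average ranks, W is the smaller
signed-rank sum, and the two-sided p-value enumerates all 2ⁿ sign
assignments (supported to n = 25; the doubling enumeration is O(2ⁿ) memory).
With six pairs and one-sided data the minimum two-sided p is 2/64 = 0.03125
— exactly what the bundled clinical benchmark comparison reproduces. No
multiple-testing correction is applied across the five k-values, matching
the benchmark protocol.

`vertfract.reference` bundles the published per-split accuracy columns of
the clinical benchmark (63 patients, 315 VBs). Only the per-split numbers
are stored; averages and test statistics are always recomputed.

## Problem sizes and known limitations

The default validation cohort (63 cases × 5 VBs, 256² images) runs the full
pipeline in a few seconds on one CPU; the test suite's heaviest oracles
(exhaustive convex-combination membership, 2ⁿ Wilcoxon enumeration) are
sized to small instances where exhaustive checking is exact.

Under the default phantom conditions the wedge deformation is separable
enough that both classifiers reach 100 % test accuracy — the
SVM-versus-KNN comparison on the phantom is therefore a tie, and the
qualitative "SVM ≥ KNN" direction is verified as such. The discriminative
ordering of classifiers on subtle clinical fractures cannot be established
from this phantom; that is a property of the harder class geometry, not of
the implementation. Other limitations: no disc/canal segmentation, no
benign-versus-malignant discrimination, no 3-D volumes, and segmentation
assumes a single roughly-vertical spine column in the field of view.
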