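# Methods

This note documents the models, algorithms and parameter choices behind
`sonoskin`, and what the phantom-based validation does and does not
demonstrate.

## Problem setting

High-frequency B-mode ultrasound shows skin lesions as hypoechoic regions in
the dermis, with diagnostically useful cues in their echotexture, border
shape and the acoustic shadow they cast.  The framework classifies a lesion
image into one of three classes — benign nevus, basal cell carcinoma (BCC),
malignant melanoma (MM) — through four stages: segmentation, region
derivation, feature extraction, and SVM classification with stratified
ten-fold cross-validation over six one-vs-one and one-vs-rest tasks.
Because clinical recordings are not distributed with the package, a phantom
generator with known ground truth drives all quantitative validation.

## Phantom generator

The phantom emulates the *statistical geometry* of a skin ultrasound frame,
not its acoustics.  An image (default 128 x 160 px, depth along rows) is a
product of a tissue echogenicity map and multiplicative speckle:

* **Layers.** A dark above-skin coupling band (mean 0.04, default 12 rows),
  a bright epidermal entry echo (0.85, 8 rows), and a dermis (0.50) filling
  the remainder.  All intensities live in [0, 1]; 8-bit quantization happens
  only on PNG export.
* **Speckle.** Exponential intensity (squared magnitude of a unit-variance
  complex Gaussian scatterer sum), blurred by a Gaussian PSF of sigma 0.8 px
  to mimic spatial speckle correlation.  Any positively skewed
  multiplicative texture would serve; this is the standard stylized choice.
* **Lesion.** A radially perturbed ellipse placed uniformly at random where
  it fits inside the dermis with a 12-row margin below.  The border
  perturbation is a random-phase sum of angular harmonics 2-5 normalized so
  its maximum radial displacement equals the `irregularity` parameter (px).
  With zero amplitude the mask is an exact discrete ellipse.
* **Heterogeneity.** Inside the lesion, an uncorrelated multiplicative
  component is mixed in: `speckle * (1 + 0.5 (h - 1)(X - 1))` with `X ~
  Exp(1)`, clipped at zero.  `h = 1` reproduces the dermis texture; larger
  values raise both variance and adjacent-pixel contrast, which the GLCM
  features pick up monotonically.
* **Shadow.** Columns under the lesion are darkened by
  `1 - s * (t_c / t_max) * exp(-d / 40)` where `s` is the shadow strength,
  `t_c` the lesion thickness crossed in that column and `d` the depth below
  the lesion.  The darkening is strongest immediately under the lesion and
  fades with depth, as depth-gain compensation does on clinical scanners;
  this keeps the shadow a local feature rather than a full-depth stripe and
  keeps the dermis-under region well defined.

Default class appearances (echogenicity relative to dermis mean /
heterogeneity / semi-axes / irregularity / shadow):

| class | echo | h   | semi-axes (ax, lat) | irregularity | shadow |
|-------|------|-----|---------------------|--------------|--------|
| nevus | 0.35 | 1.0 | 10, 18              | 0.5          | 0.0    |
| BCC   | 0.40 | 1.6 | 12, 15              | 1.5          | 0.55   |
| MM    | 0.50 | 2.2 | 11, 16              | 4.0          | 0.15   |

These are stylized qualitative signatures from the dermatologic-ultrasound
literature (homogeneous nevi; shadowing BCCs; heterogeneous, irregular MMs),
not fits to measured data — no quantitative appearance statistics per class
are published.  Consequently the phantom classes are *cleanly* separable and
cross-validated AUCs on phantoms approach 1.0; passing tests demonstrates
that the pipeline recovers known structure and invents none (the
identical-parameter null control), not that clinical-level accuracy is
reproduced.  Real images add device variability, anisotropic PSFs, off-plane
lesions and operator effects the phantom does not model.

Determinism: each sample's RNG seed derives from the dataset master seed, so
datasets are byte-identical across runs and platforms.

## Segmentation

* **Preprocessing** rescales to [0, 1] between the 1st/99th intensity
  percentiles (making the pipeline invariant to machine gain/scale) and
  applies a 3x3 median filter.
* **Layer extraction** uses 3-class multilevel Otsu thresholding; the
  geometric priors are that the above-skin band is the dark region at the
  top of each column and the epidermis is the first bright run below it.
  Per-column boundaries are median-filtered across columns (window 15).
* **Seeding** thresholds the dermis at `mean - k * std` (k = 1.0) of the
  dermis intensities, opens with a radius-2 disk, and keeps the largest
  4-connected blob (ties: shallower centroid).  Anything below 10 px is an
  error, never a degenerate mask.
* **Growing** is a morphological Chan-Vese active contour (200 iterations,
  smoothing weight 1, lambda1 = lambda2 = 1) started from the seed; the
  fully-automated path restricts evolution to the dermis band so the
  contour cannot leak into the entry echo.  The largest component
  overlapping the seed is kept and holes are filled.  The method is
  deterministic, and idempotent in the noiseless limit.
* **Semi-automated paths** replace the seed by a rasterized freehand
  polygon (pixel centers strictly inside or on the boundary) or by the
  largest-area axis-aligned rectangle (LAR) inscribed in it, computed
  exactly on the pixel grid by the histogram-stack maximal-rectangle
  algorithm with (top row, left column) tie-breaking.

Agreement uses the Dice coefficient; the success criterion against a
reference segmentation is Dice strictly greater than 0.10 — a deliberately
permissive published bar that only asks whether the automatic mask found
the lesion at all.  On 30 default phantoms the FA path scores a success rate
of 1.0 and a median Dice near 0.9 (BCC masks are the weakest because the
contour partially follows the posterior shadow).

## Regions and features

Three regions are derived from a lesion mask: the lesion `L`; the boundary
lane `LB` of pixels within `lane_width` (default 5 px, Euclidean distance)
of the contour on **both** sides (the reference description says only "a
fixed distance", so the straddling convention is this package's choice); and
the dermis-under region `D` from one row below each lesion column down to
the lesion's own height (capped by the dermis band), minus lane pixels so
the three regions probe disjoint tissue.

The 62 features follow the published index table.  Formulas for the
boundary block (idx 6-12) are evaluated exactly as printed, with sample
(ddof = 1) standard deviations and NaN for zero denominators.  The
attenuation (1-3) and radial-contrast (4-5) features are reconstructions
from their prose descriptions — the original expressions are not reprinted —
and are declared normative for this package:

* idx 1: least-squares slope of mean lesion-row intensity versus depth;
* idx 2: relative intensity deficit of `D` versus laterally flanking dermis
  at the same depths (posterior-shadow contrast);
* idx 3: std over columns of per-column intensity-depth slopes in the lesion;
* idx 4/5: std/mean over 72 rays from the lesion centroid of
  `(avg_out - avg_in) / (avg_out + avg_in)` over 5-sample segments just
  outside/inside the contour (nearest-pixel sampling, so piecewise-constant
  images give exact values).

Statistical features use sample skewness, raw (non-excess) kurtosis, and
base-2 Shannon entropy of a 64-bin histogram over the lesion's intensity
range.  Shape features come from an arc-length-resampled (400 samples)
contour smoothed with a periodic Gaussian (sigma 6 samples — large enough
that rasterization staircase noise does not dominate the curvature std,
small enough that a disk's circularity stays within 1 percent of 1);
perimeter is the smoothed polyline length, area the pixel count, and axis
lengths come from second moments.

GLCMs are computed at offset distance 1, vertically and horizontally, for
the lesion and dermis-under regions, quantized to 16 gray levels over each
region's own min-max range, counting only pixel pairs fully inside the
region, symmetrized and normalized.  The 13 descriptors use base-2
logarithms for entropy-type statistics, except the two information measures
of correlation, which keep their classic natural-log `1 - exp(-2 dH)` form.
Correlation I (moment form) and II (product form) are both evaluated from
their literal formulas and coincide for a normalized symmetric matrix.
Difference variance is the centered variance of the |i-j| distribution.

The index blocks are frozen in `feature_map.json`: lesion-horizontal 21-28,
lesion-vertical 29-41, dermis-horizontal 42-49, dermis-vertical 50-62.
The published per-descriptor index sets force this layout: the five
vertical-only descriptors (energy, entropy, both homogeneities, information
correlation II) fall in the 13-wide blocks, so the 13-wide blocks are the
vertical ones.

## Classification and evaluation

The classifier is a soft-margin linear SVM, C = 1, class-balanced weights —
the kernel and regularization were not published, and a linear kernel is
required for the SVM-weight-based feature ranking to be meaningful.  NaN
features are imputed with the training-fold median; features are
standardized with training-fold statistics.  Multiclass uses one-vs-rest
with argmax of decision values (ties to the more prevalent training class);
a binary decision score of exactly 0 predicts the negative class.

Stratified ten-fold assignment shuffles each class with the seeded
generator and deals round-robin, so per-class fold counts differ by at most
one (a 110/130/70 cohort gives exactly 11/13/7 per fold).  Sens, Spec and
ACC are means over folds; the ROC curve and AUC pool the out-of-fold
decision scores into a single curve per task — whether the original
evaluation pooled or fold-averaged its ROC is not stated, and pooling is
this package's documented choice.  The AUC implementation sweeps all score
thresholds and equals the Mann-Whitney concordance probability with half
credit for ties (verified exactly against pair counting).

Pairwise tasks in binary mode use only the two named classes; in multiclass
mode the model trains on all three classes and only samples of the two
named classes are scored, a third-class prediction counting as an error.
One-vs-others multiclass tasks are scored with predictions collapsed to
positive-vs-rest.  Both conventions are assumptions; the original scoring
of multiclass rows is not fully specified.

The leave-one-feature-out ablation re-runs the cross-validation 62 times,
each without one feature, and ranks features by the resulting ACC (or AUC)
ascending.  On phantom cohorts near ceiling performance the deltas are
small; the planted-feature synthetic-table test is the sharp version of the
recovery property.  The null control — all three classes generated with
identical parameters — is evaluated on ground-truth masks, isolating the
feature-and-classifier chain from segmentation variability; its AUC is a
noisy statistic (sd roughly 0.08 at 120 samples, with the mild pessimistic
bias typical of cross-validated classifiers on pure noise), which is why
the control asserts a broad band around 1/2 rather than a tight value.

Border sensitivity perturbs a reference mask at named border sectors
(right, bottom, both, all); a sector is the set of boundary-ring pixels
whose outward normal (gradient of a sigma-2-smoothed mask indicator) lies
within 45 degrees of the edge direction, and the perturbation is a
restricted dilation or erosion with a disk of the requested radius.  The
constructed demonstration plants a hyperechoic patch along the inside of a
nevus's right border: the patch makes the classifier call the lesion
cancerous, and a right-edge shrink of a few pixels — just enough to exclude
the patch from the lesion region — flips the call back.

## Problem sizes and numerics

Validation runs use 128 x 160 px phantoms, cohorts of 120 (40 per class)
for classification, 30 for segmentation recovery, and 10 synthetic-table
seeds for ablation recovery; these sizes keep the full suite fast while
leaving every statistic far from its decision boundary.  All randomness
flows from explicit integer seeds; repeated runs are bit-identical.
Degenerate inputs (constant images, empty masks, lesions touching the
dermis bottom, single-class folds) raise typed errors rather than
propagating NaNs; the only NaNs that flow are individually undefined
features, which the classifier imputes.

## Known limitations

* The phantom's class separability is stylized; measured accuracy on
  phantoms says nothing quantitative about clinical accuracy.
* The fully-automated seeding is a faithful-in-structure reconstruction of
  the published outline, not a bit-identical port of the original seeding
  algorithm.
* Attenuation/contrast features 1-5 are reconstructions (see above).
* BCC-like posterior shadows bias the grown contour downward; on phantoms
  this costs Dice but not classification accuracy.
* Single-lesion images only; no multi-lesion handling, no 3-D volumes.
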