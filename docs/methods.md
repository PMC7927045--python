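# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `microbeid`, in the order the pipeline runs.

## Scope and assumptions

The pipeline targets whole-mount brightfield microscopy of surface-water
microorganisms: each image shows one or more complete organism bodies whose
morphology (not texture or color) carries the class signal. Images are
treated as 2-D intensity fields in [0, 1]; RGB input is reduced to
luminance first (Rec. 709 weights via `skimage.color.rgb2gray` — the
convention is a choice, any fixed luminance weighting would serve).
Classification operates purely on per-blob shape descriptors, so the
pipeline assumes segmentation errors, not optics, dominate downstream
error.

## Preprocessing

Five steps, in fixed order:

1. **Aspect standardization.** Images are padded (never cropped or warped)
   with the median intensity until width = 1.2 × height, to one pixel of
   rounding. Padding keeps every blob's center of mass fixed, which
   cropping or anisotropic scaling would shift.
2. **Small-object removal** (`min_object_area`, default 30 px²) and
3. **irregular-object removal** (solidity < `irregularity_solidity_min`,
   default 0.15). Both operate on labeled masks. Before any real
   segmentation exists, objects are delimited by a conservative global
   Otsu threshold on the intensities, and rejected components are painted
   over with the median background intensity. The solidity default is
   deliberately permissive: filamentous organisms are legitimately
   non-convex (solidity 0.2–0.5), so only extreme outlines (thin tangles,
   scratches) fall below 0.15.
4. **Median denoising** (window 3 px, odd windows only; window 1 is the
   identity).
5. **Adaptive contrast enhancement** — CLAHE with tile 8 px and clip limit
   0.01. Constant images are passed through unchanged (CLAHE is undefined
   on them). The low clip limit bounds noise amplification in empty
   background regions.

No numeric values for the area threshold, the irregularity criterion, or
the enhancer parameters are prescribed by the problem; the defaults above
are this package's choices and are all configurable.

## Generalized segmentation

The segmenter is gated on the image's global intensity standard deviation
σ against `global_std_threshold` (default 0.1):

* σ < threshold (washed-out image): adaptive contrast → Kirsch response →
  fixed global threshold `git` (default 0.5 on the [0, 1]-rescaled
  response);
* otherwise: Kirsch response → Otsu threshold on the response.

**Kirsch response.** The eight compass kernels are the standard 3×3
pattern (5, 5, 5 / −3, 0, −3 / −3, −3, −3) rotated in 45° steps around the
border ring; the response is the maximum over the eight convolutions
(reflect padding), clipped at zero and rescaled so the image maximum is 1.
Because each ring position takes the value 5 in exactly three rotations
and −3 in five, the eight kernels sum to zero at every position, so the
directional maximum is non-negative and a constant image maps to exactly
zero (a small absolute floor, 1e−9, guards against floating-point residue
masquerading as signal).

**Thresholding.** Otsu maximizes between-class variance over a 256-bin
histogram on [0, 1]; ties take the lowest qualifying cut, and the returned
threshold is the upper edge of the chosen bin (foreground is strictly
greater). ISODATA iterates t ← (mean below t + mean at/above t)/2 to a
fixed point within half a bin (1/512) and is provided for comparison.
Constant images are rejected by both (no histogram to split).

**Edge map → solid bodies.** The thresholded edge response is a ring
around each body, and on faint or thin bodies the ring is broken where the
local gradient falls under the single global cut. The conversion is
dilation (radius 2) to bridge breaks, closing (radius 2), hole filling,
then erosion (radius 3) to compensate both the dilation and the ring's
outward half-width, followed by 8-connected labeling and small-object
removal. The radii were fixed by comparing candidate combinations on the
synthetic suite across several seeds (mean IoU ≈ 0.84 versus ≈ 0.79 for
fill-only post-processing); they are exposed on `GSAConfig`. The declared
tile size `Ts` is routed to the adaptive enhancer's tile parameter — the
one place a tile size is actually consumed.

**Filter benchmark.** Seven candidate filters are scored by drawing random
samples from an annotated dataset and counting segmentations with
IoU ≥ 0.5 against truth; the per-filter score is the *unweighted* mean of
the per-sample-size acceptance ratios (this averaging convention
reproduces the published per-filter averages from their printed counts,
e.g. (20+23+39)/(25,50,75) → 0.59). Gradient pairs combine by magnitude;
Laplacian/LoG by absolute response; mean and Gaussian low-pass return the
smoothed image itself, so thresholding them segments intensity rather
than edges.

## Blob descriptors

24 per-blob features; standard region properties come from
`skimage.measure.regionprops` (area, filled area, extent, solidity,
convex area, equivalent diameter, axis lengths, eccentricity, orientation,
Euler number, centroid, bounding box, perimeter). Conventions: 0-based
(row, col), half-open bounding boxes, orientation from the row axis in
(−π/2, π/2]. Three descriptors have no library equivalent and are defined
here:

* **extrema** — the maximum pairwise distance among the eight extremal
  boundary pixels (leftmost/rightmost on the top and bottom rows,
  topmost/bottommost on the left and right columns): a Feret-like spread
  collapsed to one scalar.
* **radii** — mean Euclidean distance from the centroid to the boundary
  pixels (pixels with a 4-neighbor outside the region). This is *not*
  equiv_diameter/2; for non-convex bodies the two diverge, which is why it
  is kept as an independent column.
* **convex_hull_1..4** — bounding box (min_row, min_col, height, width) of
  the convex hull.

These three are reconstructions of conventionally underspecified
quantities; re-analyses against externally produced tables may show
systematic offsets in exactly these columns. Perimeter defaults to the
weighted boundary-segment estimator; exact pixel-edge counting is
available via `perimeter_mode="edges"`.

## Feature selection

Min-max normalization maps each column through (x − min)/(max − min)
(constant columns to 0; the fitted transform is reapplied to unseen rows
without clipping, so out-of-fold values may leave [0, 1]). Mutual
information between each feature and the class label is estimated with
the k-nearest-neighbor estimator for continuous–discrete pairs
(`sklearn.feature_selection.mutual_info_classif`, k = 3, seeded jitter),
reported in nats and clipped at zero. MI is estimated on normalized
features by default; the transform is monotone, so this mainly pins down
the estimator's scale-dependent tie-breaking jitter, and it can be
disabled. Elimination drops the n lowest-scoring features (default n = 5,
which reproduces the published eliminated set from the published score
table), ties broken by column order; an MI-threshold rule and a PCA
baseline (orthonormal components, non-increasing explained variance) are
provided.

## The ISVM kernel

Tukey-hinge quartiles: for 2n sorted values Q1/Q3 are the medians of the n
smallest/largest; for 2n + 1 the central value is excluded from both
halves; IQR = Q3 − Q1. The literal modified kernel is

    K(X, Y)[i, j] = exp(−γ · ‖(X[i] − iqr(X)) − Y[j]‖²),  γ = 1,

where iqr(X) is the per-column IQR vector of the *first argument only*,
recomputed per call. Three consequences follow directly and are preserved
rather than repaired:

* the Gram matrix is **asymmetric** (K(X,X) ≠ K(X,X)ᵀ) and its diagonal is
  exp(−‖iqr‖²) ≠ 1 — the kernel is not Mercer;
* the shift is a **rigid translation**: subtracting one constant vector
  from every row of X cannot remove or down-weight outliers, it displaces
  each query's RBF neighborhood by ‖iqr‖ relative to the reference rows;
* with all column IQRs zero the kernel reduces exactly to the plain RBF
  with γ = 1, and the `symmetric` mode (both arguments shifted by a stored
  training IQR) is numerically identical to the plain RBF by translation
  invariance — the behavioral difference exists only in literal mode.

The classifier drives `sklearn.svm.SVC` in callable-kernel mode
(one-vs-one multiclass, the standard reduction for kernel SVMs). Because
SMO's convergence theory assumes a PSD Gram, the solver can cycle on
literal-mode problems; a hard iteration cap (`max_iter`, default 20 000
per binary subproblem, far above any converging fit) bounds runtime, and
the resulting `ConvergenceWarning`s are expected in literal mode. Options:
`gamma` exposes the γ that the literal form fixes at 1;
`freeze_train_iqr=True` reuses the training IQR at prediction time instead
of recomputing it from the query rows (deployment stability; single-row
queries always fall back to the training IQR since one row has no
quartiles).

**Empirical behavior.** On this package's Gaussian class-conditional
fixtures the literal kernel is severely *harmful*: with min-max-normalized
24-column tables the IQR vector has norm ≈ 0.6–1.3, comparable to the
between-class distances, and the displaced neighborhood structure drives
10-fold accuracy to roughly the majority-class rate while the plain RBF at
the same (γ = 1, C = 4.3) is near-perfect. The acceptance suite states the
directional expectation (literal ≥ plain on contaminated tables in a
majority of seeded runs) and currently records its failure honestly. A
consistent explanation is that published gains attributed to kernels of
this form arise from comparing against a baseline tuned to a much larger
γ (e.g. 92 from a log-grid search) while the modified kernel runs at its
implicit γ = 1 — at γ = 92 on our fixtures both variants collapse — and
from feature distributions so heavy-tailed that min-max normalization
compresses the bulk of the data and the IQR shift toward ≈ 0.

## Evaluation

Metrics are one-vs-rest precision, recall, F1 (harmonic mean), and
accuracy, reported as percentages; aggregation over classes defaults to
weighted averaging (macro available) — under heavy class imbalance
weighted averaging is what makes accuracy and precision move together.
Cross-validation is stratified k-fold (default 10, shuffled, seeded);
folds require every class to have at least k members; reports carry the
seed and an MD5 hash of the fold assignment so two runs can be compared
exactly. Random hyperparameter search samples points from per-parameter
grids (log-spaced 10⁻²..10² with 5 points for γ and C), scores each by
internal stratified CV (3 folds), and picks the best by accuracy with
precision as tie-break. Class imbalance is deliberately left to
hyperparameters; no resampling is applied.

The orchestration layer fits the scaler and the MI selection inside each
training fold by default (leakage-safe). `paper_mode=True` fits both once
on the full table before CV — the simpler protocol a single-script
analysis typically uses; the report names the protocol either way.

## Synthetic fixtures

**Images.** Four parametric archetypes cover the morphological range of
the ten target classes: `filament` (disc-swept quadratic Bézier, radius
≈ size/13), `colony` (union of 6–12 discs), `branch` (recursive segments,
two 0.4–0.8 rad splits), `ovoid` (ellipse, axis ratio ≈ 2:1). Bodies are
rendered at intensity ≈ 0.75 (±8% per body) on a 0.2 background in a
200×240 frame (already 1:1.2), placed on a jittered grid so they stay in
frame and apart; the label mask coincides exactly with the rendered
pixels. Degradation is applied separately: debris discs (radius 2–3.5 px)
placed away from bodies, Gaussian blur, additive Gaussian noise, clipping
to [0, 1]. The default benchmark suite is 20 images (5 per archetype,
2–4 bodies of size 55–75 px) with noise sd 0.02, blur sigma 1 px, and 3
debris objects — a mild, realistic degradation level fixed when the suite
was defined. Not modeled: optics (PSF, defocus layers), illumination
gradients, touching/overlapping organisms, internal structure. Passing
the IoU property therefore shows the algorithm recovers well-separated
bodies under mild noise, not that it handles crowded real slides.

**Tables.** Informative columns are class-conditional Gaussians
(means drawn N(0, separation²) per class/feature, default separation 2;
unit scales); noise columns are standard normal independent of class; a
fraction of rows is multiplied by 1 + |t₂| (heavy-tailed) to emulate
extreme-value contamination. The default layout is 19 informative + 5
noise columns reusing the canonical descriptor names, with the noise
columns placed at the positions the selection stage is expected to
eliminate, and per-class counts can mirror the study inventory at any
scale (`study_table_spec`). Gaussian class-conditionals are the standard
reading of a location-scale class model; real morphometric features are
right-skewed, which the outlier mechanism only partially emulates — a
caveat relevant to the ISVM finding above.

## Problem sizes and numerical choices

Default verification sizes: 20-image segmentation suite; n = 2000 rows ×
20 seeds for noise-feature recovery; n = 5000 for MI estimator validation
against 1-D quadrature of the two-class Gaussian mixture (tolerance 10%,
observed error well under 1%); 10 seeded repetitions of 10-fold CV at
n ≈ 500 for the classifier comparison. Convolutions use reflect padding;
Otsu uses 256 bins; ISODATA tolerance is half a bin; PCA orthonormality is
checked to 1e−8; kernel hand-values to 1e−12. All randomness flows through
per-call `numpy.random.Generator`s — no global RNG state.

## Known limitations

* Extrema, radii, and the convex-hull box are reconstructions (above);
  external tables may differ systematically in those columns.
* The literal ISVM kernel is preserved as specified, including its
  non-Mercer pathology; it should not be expected to improve on the plain
  RBF on generic data (see the empirical note above).
* The segmenter's single global threshold on the rescaled edge response
  couples all bodies in an image; one very strong edge can push faint
  bodies below the cut. The bridging dilation mitigates but does not
  eliminate this.
* Learned segmentation, texture/color features, probability calibration,
  and resampling-based imbalance handling are out of scope.
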