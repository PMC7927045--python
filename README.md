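# microbeid

Automated identification of surface-water microorganisms from whole-mount
microscopy images. The package implements a complete pipeline for
biodiversity-monitoring work where thousands of slide images of algae,
fungi, and protozoa must be turned into per-organism records and a
classifier:

1. **Preprocessing** — aspect standardization (1:1.2 by median-background
   padding), area- and irregularity-based object removal, median denoising,
   and clip-limited adaptive contrast enhancement (CLAHE).
2. **Generalized segmentation (GSA)** — the Kirsch compass edge operator
   (maximum over eight 3×3 directional convolutions) combined with
   variance-based thresholding. The route is gated on the image's global
   intensity standard deviation σ: low-contrast images take
   *enhance → Kirsch → fixed global threshold*; the rest take
   *Kirsch → Otsu*. The thresholded edge map is bridged, closed, and
   hole-filled into solid labeled bodies. A benchmark harness scores seven
   candidate filters (Kirsch, Prewitt, Sobel, Laplacian, LoG, Gaussian
   low-pass, mean) by intersection-over-union acceptance (IoU ≥ 0.5) on
   random samples.
3. **Blob morphometry** — 24 shape descriptors per connected component
   (solidity, eccentricity, equivalent diameter, extrema spread, filled
   area, extent, orientation, Euler number, bounding box, convex-hull box,
   axis lengths, perimeter, convex area, centroid, area, mean boundary
   radius), forming a 25-column feature table with the class label.
4. **Feature selection** — min-max normalization, per-feature mutual
   information I(X; class) estimated nonparametrically from k-nearest-
   neighbor distances (k = 3, nats), and elimination of the n
   lowest-scoring features (default n = 5). A PCA baseline is included.
5. **ISVM classification** — a multiclass SVM over a modified RBF kernel

   K(x, y) = exp(−γ‖(x − IQR) − y‖²),

   where IQR is the per-feature inter-quartile range (Tukey hinges:
   quartiles are medians of the lower/upper halves) of the kernel's first
   argument. In its literal form only the first argument is shifted and
   γ = 1; this yields an asymmetric, non-Mercer Gram matrix, which the
   package reproduces faithfully (with `symmetric` and `plain_rbf` modes
   for comparison) — see `docs/methods.md` for the consequences. Models are
   scored by stratified 10-fold cross-validation (accuracy, precision,
   recall, F1) with random search over log-spaced hyperparameter grids.

A synthetic-fixture module generates microbe-like images (filament, colony,
branch, ovoid archetypes) with exact ground-truth masks plus degradation
(debris, blur, noise), and feature tables with known class-conditional
structure, class imbalance matching the study inventory, injected
pure-noise features, and heavy-tailed outlier rows — so every stage is
testable without downloads.

## Worked example

```python
import numpy as np
from microbeid import (
    ImageSpec, generate_microbe_image, degrade_image,
    preprocess_image, gsa_segment, iou, extract_features,
)
from microbeid.synthetic import study_table_spec, generate_feature_table
from microbeid.selection import mi_scores, minmax_normalize, select_features
from microbeid.isvm import ISVMClassifier, cross_validate_10fold

# segment a degraded synthetic colony image and score it against truth
spec = ImageSpec(archetype="colony", count=3, noise_sd=0.02, blur_sigma=1.0,
                 debris_count=3, seed=7)
clean, truth = generate_microbe_image(spec)
img = degrade_image(clean, spec)
mask, branch = gsa_segment(preprocess_image(img))
print(f"branch={branch}  components={mask.max()}  IoU={iou(mask > 0, truth > 0):.3f}")

# MI selection and 10-fold cross-validation on a synthetic study-style table
table = generate_feature_table(study_table_spec(scale=500 / 32779, seed=7))
scores = mi_scores(table, k=3, seed=7)
sel = select_features(scores, n_drop=5)
print("dropped:", ", ".join(sel.dropped))

norm, _ = minmax_normalize(table[list(sel.kept) + ["class"]])
report = cross_validate_10fold(
    norm, lambda: ISVMClassifier(mode="plain_rbf", gamma=1.0, C=4.3), seed=7
)
print(f"10-fold SVM: accuracy={report.accuracy:.1f}%  precision={report.precision:.1f}%  "
      f"recall={report.recall:.1f}%  F1={report.f1:.1f}%")
```

Output:

```
branch=high_std  components=4  IoU=0.884
dropped: euler_number, bbox_2, bbox_3, bbox_4, convex_hull_1
10-fold SVM: accuracy=100.0%  precision=100.0%  recall=100.0%  F1=100.0%
```

The segmenter took the normal-contrast route (`high_std`), recovered the
three colonies (plus one debris object large enough to survive the area
filter) at IoU 0.884 against the known mask; the drop-5 mutual-information
rule isolated exactly the five injected noise columns; and the
cross-validated classifier separates the ten synthetic classes essentially
perfectly at this class separation.

A command-line interface mirrors the library:
`microbeid preprocess | segment | benchmark-filters | features | select |
train | evaluate | run-all | replicate` (see `--help` on each).
`microbeid replicate --features <csv>` re-analyzes a user-supplied copy of
the deposited study table (Mendeley Data doi:10.17632/f9m85ptmvc.4) and
prints recomputed MI scores and cross-validation metrics side by side with
the published reference values.

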