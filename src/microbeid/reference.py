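"""Published reference values for the ten-class surface-water microbe study.

The deposited feature table for that study is available from Mendeley Data
(doi:10.17632/f9m85ptmvc.4).  The constants below are the study's printed
summary numbers; they serve two purposes here: as *inputs* to worked examples
(e.g. recomputing benchmark averages from accepted/sample counts) and as the
comparison column printed by :func:`microbeid.pipeline.replicate_study`.
Nothing in the library's own computations depends on them.
"""

from __future__ import annotations

# Class inventory: instances per microorganism class in the deposited dataset.
CLASS_COUNTS: dict[str, int] = {
    "Spirogyra": 4012,
    "Volvox": 7002,
    "Phithophora": 2303,
    "Yeast": 4302,
    "Rhizopus": 3910,
    "Penicillium": 3410,
    "Aspergillus sp": 3230,
    "Protozoa": 1230,
    "Diatom": 1450,
    "Ulothrix": 1930,
}

CLASS_TYPES: dict[str, str] = {
    "Spirogyra": "Algae",
    "Volvox": "Algae",
    "Phithophora": "Algae",
    "Yeast": "Fungi",
    "Rhizopus": "Fungi",
    "Penicillium": "Fungi",
    "Aspergillus sp": "Fungi",
    "Protozoa": "Eukaryotes",
    "Diatom": "Algae",
    "Ulothrix": "Algae",
}

#: Morphological archetype used by the synthetic generator for each class.
CLASS_ARCHETYPES: dict[str, str] = {
    "Spirogyra": "filament",
    "Volvox": "colony",
    "Phithophora": "branch",
    "Yeast": "ovoid",
    "Rhizopus": "branch",
    "Penicillium": "branch",
    "Aspergillus sp": "branch",
    "Protozoa": "ovoid",
    "Diatom": "ovoid",
    "Ulothrix": "filament",
}

# Segmentation filter benchmark: accepted segmentations (IoU >= 0.5) out of
# random samples of size 25 / 50 / 75, and the printed per-filter average.
FILTER_SAMPLE_SIZES: tuple[int, ...] = (25, 50, 75)
FILTER_BENCHMARK: dict[str, tuple[int, int, int]] = {
    "prewitt": (20, 23, 39),
    "log": (13, 31, 39),
    "laplacian": (15, 39, 67),
    "gaussian_lowpass": (14, 38, 66),
    "sobel": (19, 36, 69),
    "mean": (20, 40, 68),
    "kirsch": (22, 45, 70),
}
FILTER_AVERAGE_ACCURACY: dict[str, float] = {
    "prewitt": 0.59,
    "log": 0.55,
    "laplacian": 0.76,
    "gaussian_lowpass": 0.73,
    "sobel": 0.80,
    "mean": 0.84,
    "kirsch": 0.90,
}

# Thresholding comparison: per-round accepted/sample accuracies for the two
# clustering methods (sample sizes 10, 30, 40, 50, 100).
OTSU_ROUND_ACCURACIES: tuple[float, ...] = (1.0, 0.93, 0.90, 0.79, 0.79)
OTSU_AVERAGE_ACCURACY: float = 0.88
ISODATA_ROUND_ACCURACIES: tuple[float, ...] = (1.0, 0.83, 0.90, 0.62, 0.73)

# Estimated mutual information (nats, kNN estimator with k=3) per feature,
# as published for the deposited table.
MI_REFERENCE: dict[str, float] = {
    "solidity": 1.686472,
    "eccentricity": 1.669454,
    "equiv_diameter": 1.576661,
    "extrema": 1.091982,
    "filled_area": 1.606655,
    "extent": 1.697518,
    "orientation": 1.723908,
    "euler_number": 0.539431,
    "bbox_1": 1.091185,
    "bbox_2": 0.970946,
    "bbox_3": 0.656073,
    "bbox_4": 0.666515,
    "convex_hull_1": 1.078976,
    "convex_hull_2": 1.08001,
    "convex_hull_3": 1.109029,
    "convex_hull_4": 1.18575,
    "major_axis": 1.748819,
    "minor_axis": 1.744697,
    "perimeter": 1.735635,
    "convex_area": 1.68434,
    "centroid_1": 1.744533,
    "centroid_2": 1.721187,
    "area": 1.578785,
    "radii": 2.10396,
}

#: Features the study eliminated as carrying the lowest information gain.
DROPPED_FEATURES: tuple[str, ...] = (
    "euler_number",
    "bbox_2",
    "bbox_3",
    "bbox_4",
    "convex_hull_1",
)

# Best SVM-radial hyperparameters found by random grid search in the study.
SVM_BEST_GAMMA: float = 92.0
SVM_BEST_C: float = 4.3

# Headline 10-fold cross-validation metrics (percent).
SVM_CV_METRICS: dict[str, float] = {
    "accuracy": 96.1, "precision": 96.2, "recall": 96.1, "f1": 96.1,
}
ISVM_CV_METRICS: dict[str, float] = {
    "accuracy": 98.2, "precision": 98.2, "recall": 98.1, "f1": 98.1,
}

TOTAL_INSTANCES: int = 32779
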