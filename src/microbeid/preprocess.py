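"""Image cleanup preceding segmentation.

Five steps, applied in this order by :func:`preprocess_image`:

1. aspect standardization to height:width = 1:1.2 by symmetric padding,
2. removal of objects below a configurable area,
3. removal of highly irregular objects (low convex-hull solidity),
4. median denoising,
5. adaptive (tile-based, clip-limited) contrast enhancement.

The two object-removal steps need objects delimited before any real
segmentation has happened; a conservative provisional foreground mask is
obtained by global Otsu thresholding of the intensities, and the pixels of
rejected components are painted over with the median background intensity.
The mask-level operations are also exposed directly for use on final
segmentations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, filters, measure


@dataclass
class PreprocessConfig:
    target_aspect: float = 1.2  # width / height
    min_object_area: int = 30
    irregularity_solidity_min: float = 0.15
    median_window: int = 3
    clahe_tile: int = 8
    clahe_clip: float = 0.01

    def __post_init__(self) -> None:
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError("median_window must be odd and >= 1")
        if not 0.0 <= self.irregularity_solidity_min <= 1.0:
            raise ValueError("irregularity_solidity_min must lie in [0, 1]")
        if self.min_object_area < 0:
            raise ValueError("min_object_area must be >= 0")


def standardize_aspect(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Pad symmetrically with the median intensity until width = 1.2 * height.

    Padding (rather than cropping or warping) keeps blob centers of mass
    where they were.
    """
    cfg = cfg or PreprocessConfig()
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    h, w = img.shape
    fill = float(np.median(img))
    target_w = int(round(h * cfg.target_aspect))
    if w < target_w:
        pad = target_w - w
        img = np.pad(img, ((0, 0), (pad // 2, pad - pad // 2)), constant_values=fill)
    elif w > target_w:
        target_h = int(round(w / cfg.target_aspect))
        pad = target_h - h
        if pad > 0:
            img = np.pad(img, ((pad // 2, pad - pad // 2), (0, 0)), constant_values=fill)
    return img


def _compact_labels(labels: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Zero out labels not in ``keep`` and relabel survivors 1..K in order."""
    mapping = np.zeros(labels.max() + 1, dtype=labels.dtype)
    mapping[keep] = np.arange(1, len(keep) + 1)
    return mapping[labels]


def remove_small_objects(mask: np.ndarray, min_area: int) -> np.ndarray:
    """Drop components with pixel area below ``min_area``; relabel 1..K."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    mask = np.asarray(mask)
    if mask.max() < 1:
        return mask.copy()
    areas = np.bincount(mask.ravel())
    keep = np.flatnonzero(areas >= min_area)
    keep = keep[keep > 0]
    return _compact_labels(mask, keep)


def remove_irregular_objects(mask: np.ndarray, solidity_min: float) -> np.ndarray:
    """Drop components whose solidity (area / convex area) is below threshold."""
    if not 0.0 <= solidity_min <= 1.0:
        raise ValueError("solidity_min must lie in [0, 1]")
    mask = np.asarray(mask)
    if mask.max() < 1 or solidity_min == 0.0:
        return mask.copy()
    keep = [
        r.label for r in measure.regionprops(mask) if r.solidity >= solidity_min
    ]
    return _compact_labels(mask, np.asarray(keep, dtype=mask.dtype))


def median_denoise(img: np.ndarray, window: int = 3) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("median window must be odd and >= 1")
    img = np.asarray(img, dtype=float)
    if window == 1:
        return img.copy()
    return np.clip(ndimage.median_filter(img, size=window), 0.0, 1.0)


def adaptive_contrast(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Tile-based clip-limited histogram equalization (CLAHE)."""
    cfg = cfg or PreprocessConfig()
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        return img.copy()
    out = exposure.equalize_adapthist(
        img, kernel_size=cfg.clahe_tile, clip_limit=cfg.clahe_clip
    )
    return np.clip(out, 0.0, 1.0)


def provisional_foreground(img: np.ndarray) -> np.ndarray:
    """Conservative object delimitation for the pre-segmentation cleanup.

    Global Otsu on intensity; blank (constant) images yield an empty mask.
    """
    img = np.asarray(img, dtype=float)
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)
    fg = img > filters.threshold_otsu(img)
    labels, _ = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    return labels.astype(np.int32)


def preprocess_image(img: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Run the full five-step cleanup on an intensity image in [0, 1]."""
    cfg = cfg or PreprocessConfig()
    img = standardize_aspect(img, cfg)
    labels = provisional_foreground(img)
    if labels.max() > 0:
        kept = remove_small_objects(labels, cfg.min_object_area)
        kept = remove_irregular_objects(kept, cfg.irregularity_solidity_min)
        rejected = (labels > 0) & (kept == 0)
        if rejected.any():
            background = img[labels == 0]
            fill = float(np.median(background)) if background.size else float(np.median(img))
            img = img.copy()
            img[rejected] = fill
    img = median_denoise(img, cfg.median_window)
    return adaptive_contrast(img, cfg)
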