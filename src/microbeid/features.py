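"""Per-blob morphological descriptors.

Each connected foreground component ("blob") of a segmented image yields one
row of 24 shape descriptors; together with the class label this forms the
25-column feature table consumed by the selection and classification stages.

Standard region properties are delegated to
:func:`skimage.measure.regionprops`; three descriptors without a library
equivalent are computed here:

* ``extrema`` — the maximum pairwise distance among the eight extremal
  boundary points (a Feret-like spread collapsed to one scalar);
* ``radii`` — the mean distance from the centroid to the boundary pixels;
* ``convex_hull_1..4`` — the bounding box (min_row, min_col, height, width)
  of the convex hull.

Conventions: 0-based (row, col) coordinates, half-open bounding boxes,
orientation measured from the row axis in (−π/2, π/2].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

#: Canonical order of the 24 descriptor columns; the table's 25th column is
#: the class label.
FEATURE_NAMES: tuple[str, ...] = (
    "solidity",
    "eccentricity",
    "equiv_diameter",
    "extrema",
    "filled_area",
    "extent",
    "orientation",
    "euler_number",
    "bbox_1",
    "bbox_2",
    "bbox_3",
    "bbox_4",
    "convex_hull_1",
    "convex_hull_2",
    "convex_hull_3",
    "convex_hull_4",
    "major_axis",
    "minor_axis",
    "perimeter",
    "convex_area",
    "centroid_1",
    "centroid_2",
    "area",
    "radii",
)

TABLE_COLUMNS: tuple[str, ...] = FEATURE_NAMES + ("class",)


def label_blobs(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Label connected foreground components under 4- or 8-connectivity."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask)
    return measure.label(mask > 0, connectivity=1 if connectivity == 4 else 2)


def _extremal_points(coords: np.ndarray) -> np.ndarray:
    """The 8 extremal pixels: leftmost/rightmost at top/bottom rows, and
    topmost/bottommost at left/right columns."""
    pts = []
    for axis in (0, 1):
        for reducer in (np.min, np.max):
            v = reducer(coords[:, axis])
            sel = coords[coords[:, axis] == v]
            other = 1 - axis
            pts.append(sel[np.argmin(sel[:, other])])
            pts.append(sel[np.argmax(sel[:, other])])
    return np.asarray(pts, dtype=float)


def _extrema_spread(coords: np.ndarray) -> float:
    pts = _extremal_points(coords)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


def _boundary_pixels(region_image: np.ndarray) -> np.ndarray:
    """Pixels of the region with at least one 4-neighbor outside it."""
    interior = ndimage.binary_erosion(
        region_image, structure=ndimage.generate_binary_structure(2, 1)
    )
    boundary = region_image & ~interior
    return np.argwhere(boundary)


def _edge_count_perimeter(region_image: np.ndarray) -> float:
    """Exact count of pixel edges between the region and its complement."""
    padded = np.pad(region_image.astype(int), 1)
    edges = 0
    for axis in (0, 1):
        edges += np.abs(np.diff(padded, axis=axis)).sum()
    return float(edges)


def extract_features(
    labeled: np.ndarray,
    connectivity: int = 8,
    class_label: str | None = None,
    perimeter_mode: str = "weighted",
) -> pd.DataFrame:
    """One descriptor row per labeled component.

    ``perimeter_mode``: ``"weighted"`` uses the weighted boundary-segment
    estimator; ``"edges"`` counts pixel edges exactly.
    """
    labeled = np.asarray(labeled)
    if labeled.max() < 1:
        raise ValueError("mask contains no components")
    if perimeter_mode not in ("weighted", "edges"):
        raise ValueError("perimeter_mode must be 'weighted' or 'edges'")

    rows = []
    for region in measure.regionprops(labeled):
        minr, minc, maxr, maxc = region.bbox
        hull_img = region.image_convex
        hr, hc = np.nonzero(hull_img)
        coords = region.coords
        boundary = _boundary_pixels(region.image)
        centroid_local = np.asarray(region.centroid) - (minr, minc)
        radii = float(
            np.sqrt(((boundary - centroid_local) ** 2).sum(1)).mean()
        ) if len(boundary) else 0.0
        if perimeter_mode == "weighted":
            perim = float(region.perimeter)
        else:
            perim = _edge_count_perimeter(region.image)
        rows.append(
            {
                "solidity": float(region.solidity),
                "eccentricity": float(region.eccentricity),
                "equiv_diameter": float(region.equivalent_diameter_area),
                "extrema": _extrema_spread(coords),
                "filled_area": float(region.area_filled),
                "extent": float(region.extent),
                "orientation": float(region.orientation),
                "euler_number": float(region.euler_number),
                "bbox_1": float(minr),
                "bbox_2": float(minc),
                "bbox_3": float(maxr - minr),
                "bbox_4": float(maxc - minc),
                "convex_hull_1": float(minr + hr.min()),
                "convex_hull_2": float(minc + hc.min()),
                "convex_hull_3": float(hr.max() - hr.min() + 1),
                "convex_hull_4": float(hc.max() - hc.min() + 1),
                "major_axis": float(region.axis_major_length),
                "minor_axis": float(region.axis_minor_length),
                "perimeter": perim,
                "convex_area": float(region.area_convex),
                "centroid_1": float(region.centroid[0]),
                "centroid_2": float(region.centroid[1]),
                "area": float(region.area),
                "radii": radii,
            }
        )
    df = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if class_label is not None:
        df["class"] = class_label
    return df


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the 25-column table as CSV (lossless float round-trip)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    missing = [c for c in TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")
    table = table[list(TABLE_COLUMNS)]
    table.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table is missing columns: {missing}")
    return df
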