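"""Synthetic microscopy fixtures with known ground truth.

Two families of generators:

* **Images** — microbe-like bodies rendered onto a dark field, one of four
  parametric archetypes (``filament`` = thick Bezier curve, ``colony`` =
  disc cluster, ``branch`` = recursive segments, ``ovoid`` = ellipse),
  together with the exact label mask of the rendered bodies.  A separate
  degradation step adds debris, blur and sensor noise so the cleanup and
  segmentation stages have real work to do.
* **Feature tables** — rows drawn from class-conditional Gaussians with a
  configurable number of informative (class-dependent) and pure-noise
  (class-independent) columns, optional class imbalance mirroring the study
  inventory, and optional heavy-tailed row contamination.

All randomness flows through one :class:`numpy.random.Generator` seeded per
call; the same spec and seed always reproduce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import reference
from .features import FEATURE_NAMES

ARCHETYPES = ("filament", "colony", "branch", "ovoid")

BACKGROUND_INTENSITY = 0.2
FOREGROUND_INTENSITY = 0.75


@dataclass(frozen=True)
class ImageSpec:
    """Parameters for one synthetic microscopy image."""

    archetype: str = "ovoid"
    count: int = 3
    size_px: float = 60.0
    shape: tuple[int, int] = (200, 240)
    noise_sd: float = 0.0
    debris_count: int = 0
    blur_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.noise_sd < 0 or self.blur_sigma < 0 or self.debris_count < 0:
            raise ValueError("degradation parameters must be >= 0")
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("image dimensions must be positive")
        if self.size_px <= 0:
            raise ValueError("size_px must be positive")


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _ellipse_mask(shape, center, a, b, theta):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _thick_path(shape, points, radius):
    """Union of discs swept along a polyline given as (row, col) points."""
    out = np.zeros(shape, dtype=bool)
    for r, c in points:
        out |= _disk_mask(shape, (r, c), radius)
    return out


def _draw_ovoid(shape, center, size, rng):
    a = size / 2.0
    b = size / 4.0 * rng.uniform(0.8, 1.2)
    theta = rng.uniform(0, math.pi)
    return _ellipse_mask(shape, center, a, b, theta)


def _draw_colony(shape, center, size, rng):
    n_discs = rng.integers(6, 13)
    spread = size / 3.0
    r_disc = size / 6.0
    out = _disk_mask(shape, center, r_disc)
    for _ in range(n_discs):
        ang = rng.uniform(0, 2 * math.pi)
        rad = rng.uniform(0, spread)
        c = (center[0] + rad * math.sin(ang), center[1] + rad * math.cos(ang))
        out |= _disk_mask(shape, c, r_disc)
    return out


def _bezier(p0, p1, p2, n=80):
    t = np.linspace(0.0, 1.0, n)[:, None]
    pts = (1 - t) ** 2 * np.asarray(p0) + 2 * (1 - t) * t * np.asarray(p1) + t**2 * np.asarray(p2)
    return [tuple(p) for p in pts]


def _draw_filament(shape, center, size, rng):
    half = size / 2.0
    ang = rng.uniform(0, math.pi)
    d = np.array([math.sin(ang), math.cos(ang)])
    p0 = np.asarray(center) - half * d
    p2 = np.asarray(center) + half * d
    normal = np.array([-d[1], d[0]])
    p1 = np.asarray(center) + rng.uniform(-0.4, 0.4) * size * normal
    radius = max(3.5, size / 13.0)
    return _thick_path(shape, _bezier(p0, p1, p2), radius)


def _draw_branch(shape, center, size, rng, depth=2):
    radius = max(3.0, size / 15.0)
    out = np.zeros(shape, dtype=bool)

    def grow(start, ang, length, level):
        nonlocal out
        end = (start[0] + length * math.sin(ang), start[1] + length * math.cos(ang))
        n = max(int(length), 2)
        pts = [
            (start[0] + (end[0] - start[0]) * t, start[1] + (end[1] - start[1]) * t)
            for t in np.linspace(0, 1, n)
        ]
        out |= _thick_path(shape, pts, radius)
        if level < depth:
            for sign in (-1.0, 1.0):
                grow(end, ang + sign * rng.uniform(0.4, 0.8), length * 0.6, level + 1)

    base_ang = rng.uniform(0, 2 * math.pi)
    grow(center, base_ang, size / 2.2, 0)
    return out


_DRAWERS = {
    "ovoid": _draw_ovoid,
    "colony": _draw_colony,
    "branch": _draw_branch,
    "filament": _draw_filament,
}


def _body_centers(spec: ImageSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Jittered grid placement keeping bodies inside the frame and apart."""
    h, w = spec.shape
    margin = spec.size_px / 2.0 + 4
    n = spec.count
    if n == 0:
        return []
    cols = int(math.ceil(math.sqrt(n * w / h)))
    rows = int(math.ceil(n / cols))
    cells = [(i, j) for i in range(rows) for j in range(cols)]
    order = rng.permutation(len(cells))[:n]
    centers = []
    for idx in order:
        i, j = cells[idx]
        r0 = margin + i * (h - 2 * margin) / max(rows, 1)
        c0 = margin + j * (w - 2 * margin) / max(cols, 1)
        jr = rng.uniform(-6, 6)
        jc = rng.uniform(-6, 6)
        centers.append(
            (
                float(np.clip(r0 + jr, margin, h - margin)),
                float(np.clip(c0 + jc, margin, w - margin)),
            )
        )
    return centers


def generate_microbe_image(spec: ImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render ``spec.count`` bodies; return (image in [0,1], label mask).

    Mask labels run 1..count and coincide exactly with the rendered pixels;
    degradation (noise, blur, debris) is applied separately by
    :func:`degrade_image` so the ground truth stays pristine.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    img = np.full((h, w), BACKGROUND_INTENSITY, dtype=float)
    mask = np.zeros((h, w), dtype=np.int32)
    drawer = _DRAWERS[spec.archetype]
    for label, center in enumerate(_body_centers(spec, rng), start=1):
        body = drawer((h, w), center, spec.size_px, rng)
        body &= mask == 0  # keep earlier labels if bodies graze each other
        if not body.any():  # degenerate placement; fall back to a disc
            body = _disk_mask((h, w), center, spec.size_px / 4) & (mask == 0)
        mask[body] = label
        img[body] = FOREGROUND_INTENSITY * rng.uniform(0.92, 1.08)
    return np.clip(img, 0.0, 1.0), mask


def degrade_image(img: np.ndarray, spec: ImageSpec) -> np.ndarray:
    """Add debris bodies, Gaussian blur and additive noise per ``spec``.

    With ``debris_count == 0``, ``blur_sigma == 0`` and ``noise_sd == 0``
    the input is returned unchanged.
    """
    img = np.asarray(img, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("input image must lie in [0, 1]")
    out = img.copy()
    rng = np.random.default_rng(spec.seed + 1)

    if spec.debris_count > 0:
        occupied = ndimage.binary_dilation(
            img > BACKGROUND_INTENSITY + 0.1, iterations=8
        )
        h, w = img.shape
        placed = 0
        attempts = 0
        while placed < spec.debris_count and attempts < 500:
            attempts += 1
            r = rng.uniform(8, h - 8)
            c = rng.uniform(8, w - 8)
            radius = rng.uniform(2.0, 3.5)
            blob = _disk_mask(img.shape, (r, c), radius)
            if (blob & occupied).any():
                continue
            out[blob] = FOREGROUND_INTENSITY * rng.uniform(0.8, 1.0)
            occupied |= ndimage.binary_dilation(blob, iterations=6)
            placed += 1

    if spec.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, spec.blur_sigma)
    if spec.noise_sd > 0:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def default_segmentation_suite(
    seed: int = 0, n_per_archetype: int = 5
) -> list[tuple[np.ndarray, np.ndarray, ImageSpec]]:
    """The standard benchmark suite: degraded image, truth mask, spec.

    Five images per archetype by default (20 total), with mild realistic
    degradation: additive noise sd 0.02, blur sigma 1 px, 3 debris objects.
    """
    base = np.random.default_rng(seed)
    suite = []
    for archetype in ARCHETYPES:
        for _ in range(n_per_archetype):
            spec = ImageSpec(
                archetype=archetype,
                count=int(base.integers(2, 5)),
                size_px=float(base.uniform(55, 75)),
                noise_sd=0.02,
                debris_count=3,
                blur_sigma=1.0,
                seed=int(base.integers(0, 2**31 - 1)),
            )
            clean, mask = generate_microbe_image(spec)
            suite.append((degrade_image(clean, spec), mask, spec))
    return suite


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


@dataclass
class TableSpec:
    """Parameters for a synthetic class-conditional feature table.

    With the default 19 informative + 5 noise columns the table reuses the
    canonical 24 descriptor names, with the noise columns placed at the
    positions the study eliminated; other dimensionalities get generic
    ``f01..`` / ``noise01..`` names.
    """

    class_names: tuple[str, ...] = tuple(reference.CLASS_COUNTS)
    n_per_class: tuple[int, ...] = (100,) * 10
    informative_dim: int = 19
    noise_dim: int = 5
    class_means: np.ndarray | None = None
    class_scales: np.ndarray | None = None
    separation: float = 2.0
    separable: bool = False
    outlier_frac: float = 0.0
    seed: int = 0
    feature_names: tuple[str, ...] = field(init=False)
    noise_features: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.class_names) != len(self.n_per_class):
            raise ValueError("class_names and n_per_class lengths differ")
        if any(n < 0 for n in self.n_per_class):
            raise ValueError("class counts must be >= 0")
        if self.informative_dim < 0 or self.noise_dim < 0:
            raise ValueError("feature dimensions must be >= 0")
        if self.separable and self.informative_dim == 0:
            raise ValueError("a separable table needs informative features")
        if not 0.0 <= self.outlier_frac <= 1.0:
            raise ValueError("outlier_frac must lie in [0, 1]")
        if self.informative_dim == 19 and self.noise_dim == 5:
            noise = reference.DROPPED_FEATURES
            informative = tuple(f for f in FEATURE_NAMES if f not in noise)
            names = tuple(FEATURE_NAMES)
        else:
            informative = tuple(f"f{i + 1:02d}" for i in range(self.informative_dim))
            noise = tuple(f"noise{i + 1:02d}" for i in range(self.noise_dim))
            names = informative + noise
        self.feature_names = names
        self.noise_features = tuple(noise)
        self._informative = informative

    @property
    def n_features(self) -> int:
        return self.informative_dim + self.noise_dim


def generate_feature_table(spec: TableSpec) -> pd.DataFrame:
    """Draw a feature table with known class structure.

    Informative columns are class-conditional Gaussians; noise columns are
    standard normal independently of the class.  A fraction
    ``spec.outlier_frac`` of rows is multiplied by a heavy-tailed
    (t-distributed) factor to emulate extreme-value contamination.
    """
    rng = np.random.default_rng(spec.seed)
    n_classes = len(spec.class_names)
    d = spec.informative_dim

    means = spec.class_means
    if means is None:
        if spec.separable:
            means = 10.0 * np.arange(n_classes)[:, None] * np.ones((1, d))
        else:
            means = rng.normal(0.0, spec.separation, size=(n_classes, d))
    means = np.asarray(means, dtype=float).reshape(n_classes, d) if d else np.zeros((n_classes, 0))
    scales = spec.class_scales
    if scales is None:
        scales = np.ones((n_classes, d))
    scales = np.asarray(scales, dtype=float).reshape(n_classes, d) if d else np.zeros((n_classes, 0))

    blocks = []
    labels = []
    for ci, (name, n) in enumerate(zip(spec.class_names, spec.n_per_class)):
        inf = rng.normal(means[ci], scales[ci], size=(n, d)) if d else np.empty((n, 0))
        noi = rng.normal(0.0, 1.0, size=(n, spec.noise_dim))
        blocks.append(np.hstack([inf, noi]))
        labels.extend([name] * n)
    X = np.vstack(blocks) if blocks else np.empty((0, spec.n_features))

    if spec.outlier_frac > 0 and len(X):
        k = int(round(spec.outlier_frac * len(X)))
        rows = rng.choice(len(X), size=k, replace=False)
        factors = 1.0 + np.abs(rng.standard_t(df=2, size=k))
        X[rows] *= factors[:, None]

    # interleave informative/noise columns into the declared name order
    cols = {}
    inf_names = list(spec._informative)
    for j, name in enumerate(inf_names):
        cols[name] = X[:, j]
    for j, name in enumerate(spec.noise_features):
        cols[name] = X[:, d + j]
    df = pd.DataFrame({name: cols[name] for name in spec.feature_names})
    df["class"] = pd.Categorical(labels, categories=list(spec.class_names))
    perm = rng.permutation(len(df))
    df = df.iloc[perm].reset_index(drop=True)
    df.attrs["noise_features"] = list(spec.noise_features)
    return df


def study_table_spec(
    scale: float = 0.05, seed: int = 0, outlier_frac: float = 0.0, **kwargs
) -> TableSpec:
    """A :class:`TableSpec` mirroring the study's class imbalance.

    ``scale`` rescales the per-class instance counts (default 1/20 of the
    deposited inventory).
    """
    counts = tuple(int(round(c * scale)) for c in reference.CLASS_COUNTS.values())
    return TableSpec(
        class_names=tuple(reference.CLASS_COUNTS),
        n_per_class=counts,
        seed=seed,
        outlier_frac=outlier_frac,
        **kwargs,
    )
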