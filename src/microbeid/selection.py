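"""Feature normalization and mutual-information-based selection.

Mutual information between each continuous descriptor and the discrete class
label is estimated nonparametrically from k-nearest-neighbor distances
(k = 3 by default), in nats, on min-max-normalized features.  Selection then
drops the n lowest-scoring features (n = 5 reproduces the study's dropped
set from its published score table); a score-threshold rule and a PCA
baseline are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.feature_selection import mutual_info_classif
from sklearn.preprocessing import MinMaxScaler


def _feature_frame(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in table.columns if c != "class"]
    frame = table[cols]
    bad = [c for c in cols if not pd.api.types.is_numeric_dtype(frame[c])]
    if bad:
        raise ValueError(f"non-numeric feature columns: {bad}")
    return frame


@dataclass
class MinMaxState:
    """Fitted column-wise min-max transform, reusable on unseen rows."""

    columns: list[str]
    scaler: MinMaxScaler

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in self.columns if c not in table.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        out = table.copy()
        out[self.columns] = self.scaler.transform(table[self.columns])
        return out


def minmax_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, MinMaxState]:
    """Map each feature column to [0, 1] by (x - min) / (max - min).

    Constant columns map to 0.  The returned state applies the identical
    affine transform to unseen rows without clipping, so out-of-range values
    may fall outside [0, 1].
    """
    frame = _feature_frame(table)
    scaler = MinMaxScaler(clip=False)
    scaled = scaler.fit_transform(frame)
    out = table.copy()
    out[frame.columns] = scaled
    return out, MinMaxState(columns=list(frame.columns), scaler=scaler)


def estimate_mi(
    feature: np.ndarray, labels: np.ndarray, k: int = 3, seed: int = 0
) -> float:
    """kNN mutual-information estimate (nats) between a continuous feature
    and a discrete class label; small negative estimates clip to 0."""
    feature = np.asarray(feature, dtype=float).ravel()
    labels = np.asarray(labels)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(feature) != len(labels):
        raise ValueError("feature and labels lengths differ")
    if len(feature) <= k + 1:
        raise ValueError("need more than k + 1 samples")
    counts = pd.Series(labels).value_counts()
    if k >= counts.min():
        raise ValueError("k must be smaller than the smallest class stratum")
    mi = mutual_info_classif(
        feature.reshape(-1, 1), labels, n_neighbors=k, random_state=seed
    )[0]
    return float(max(mi, 0.0))


@dataclass
class MIScoreTable:
    scores: pd.DataFrame  # columns: feature, mi
    k_neighbors: int
    seed: int

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.scores["feature"], self.scores["mi"]))


def mi_scores(
    table: pd.DataFrame, k: int = 3, seed: int = 0, normalize: bool = True
) -> MIScoreTable:
    """Per-feature MI against the ``class`` column.

    Features are min-max normalized first by default (the transform is
    monotone, but the estimator's tie-breaking jitter is scale-dependent).
    """
    if "class" not in table.columns:
        raise ValueError("table has no 'class' column")
    work = minmax_normalize(table)[0] if normalize else table
    frame = _feature_frame(work)
    y = np.asarray(table["class"])
    mi = mutual_info_classif(
        frame.to_numpy(), y, n_neighbors=k, random_state=seed
    )
    mi = np.maximum(mi, 0.0)
    return MIScoreTable(
        scores=pd.DataFrame({"feature": list(frame.columns), "mi": mi}),
        k_neighbors=k,
        seed=seed,
    )


@dataclass
class SelectionResult:
    kept: tuple[str, ...]
    dropped: tuple[str, ...]
    rule: str


def select_features(
    scores: MIScoreTable | dict[str, float],
    rule: str = "drop_n_lowest",
    n_drop: int = 5,
    mi_threshold: float | None = None,
) -> SelectionResult:
    """Deterministic elimination from an MI score table.

    ``drop_n_lowest`` removes exactly the ``n_drop`` smallest-MI features
    (ties broken by column order); ``mi_threshold`` drops every feature
    scoring strictly below the threshold.
    """
    if isinstance(scores, MIScoreTable):
        items = list(zip(scores.scores["feature"], scores.scores["mi"]))
    else:
        items = list(scores.items())
    names = [n for n, _ in items]
    values = np.array([v for _, v in items], dtype=float)
    if rule == "drop_n_lowest":
        if n_drop >= len(names):
            raise ValueError("n_drop must be smaller than the feature count")
        order = np.argsort(values, kind="stable")
        dropped_idx = sorted(order[:n_drop])
    elif rule == "mi_threshold":
        if mi_threshold is None:
            raise ValueError("mi_threshold rule needs a threshold")
        dropped_idx = [i for i, v in enumerate(values) if v < mi_threshold]
        if len(dropped_idx) == len(names):
            raise ValueError("threshold would drop every feature")
    else:
        raise ValueError(f"unknown rule {rule!r}")
    dropped = tuple(names[i] for i in dropped_idx)
    kept = tuple(n for n in names if n not in dropped)
    return SelectionResult(kept=kept, dropped=dropped, rule=rule)


def pca_transform(
    table: pd.DataFrame, n_components: int
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Project features onto principal components.

    Returns (transformed table, explained variance ratios, components);
    the class column, if present, is carried through untouched.
    """
    if n_components <= 0:
        raise ValueError("n_components must be positive")
    frame = _feature_frame(table)
    if n_components > frame.shape[1]:
        raise ValueError("n_components exceeds the feature count")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(frame.to_numpy())
    out = pd.DataFrame(
        scores, columns=[f"pc{i + 1}" for i in range(n_components)], index=table.index
    )
    if "class" in table.columns:
        out["class"] = table["class"].to_numpy()
    return out, pca.explained_variance_ratio_, pca.components_
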