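"""Unsupervised grouping of blobs and cross-dataset group matching.

Blobs are clustered in z-scored 28-feature space with k-means (default
k = 4, matching the four Cav1 domain classes; ``k="auto"`` selects k over
2..8 by silhouette).  Groups from two collections are matched by the
Euclidean distance between their group centers computed in a feature space
z-scored with statistics pooled over both collections; the per-column
argmin is the closest matching group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .features import FEATURE_NAMES

#: restarts for every k-means fit
KMEANS_RESTARTS = 20

AUTO_K_RANGE = range(2, 9)


@dataclass
class GroupModel:
    """Learned blob groups: labels, per-group centers, normalization."""

    labels: np.ndarray              # group id per blob, 0..k-1
    centers: np.ndarray             # (k, 28) in this model's z-scored space
    normalization: tuple            # (mean, sd) per feature
    k: int
    group_names: list
    features_raw: np.ndarray        # (n, 28) raw feature matrix

    @property
    def n_blobs(self) -> int:
        return len(self.labels)

    def centers_raw(self) -> np.ndarray:
        """Group centers in raw (unnormalized) feature units."""
        return np.vstack([self.features_raw[self.labels == g].mean(axis=0)
                          for g in range(self.k)])

    def to_frame(self, ids=None) -> pd.DataFrame:
        frame = pd.DataFrame({"group": self.labels,
                              "group_name": [self.group_names[g]
                                             for g in self.labels]})
        if ids is not None:
            frame.insert(0, "id", list(ids))
        return frame


@dataclass
class MatchMatrix:
    """Pairwise Euclidean distances between group centers of two collections.

    ``distances`` rows are groups of collection A, columns groups of
    collection B; ``best_match`` maps each column to the row label with the
    smallest distance.
    """

    distances: pd.DataFrame
    best_match: dict

    def __getitem__(self, key):
        return self.distances.loc[key]


def _as_matrix(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        features = features[list(FEATURE_NAMES)]
    mat = np.asarray(features, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected (n, {len(FEATURE_NAMES)}) feature matrix")
    return mat


def zscore(mat: np.ndarray, mean=None, sd=None):
    """Z-score columns; constant columns (sd = 0) map to 0."""
    if mean is None:
        mean = mat.mean(axis=0)
    if sd is None:
        sd = mat.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    z = (mat - mean) / safe
    z[:, sd == 0] = 0.0
    return z, mean, sd


def learn_groups(features, k: int | str = 4, seed: int = 0,
                 group_names=None) -> GroupModel:
    """Cluster blobs into k groups by k-means on z-scored features.

    ``k="auto"`` selects k in 2..8 by the silhouette score.  Groups are
    ordered by descending mean localization count (caveolae-like group
    first) and named G1..Gk unless ``group_names`` is given.
    """
    mat = _as_matrix(features)
    n = len(mat)
    if n == 0:
        raise ValueError("no blobs to cluster")
    z, mean, sd = zscore(mat)

    if k == "auto" or k == "AUTO":
        best_k, best_score = None, -np.inf
        for kk in AUTO_K_RANGE:
            if kk >= n:
                break
            fit = KMeans(n_clusters=kk, n_init=KMEANS_RESTARTS,
                         random_state=seed).fit(z)
            score = silhouette_score(z, fit.labels_)
            if score > best_score:
                best_k, best_score = kk, score
        if best_k is None:
            raise ValueError("too few blobs for automatic k selection")
        k = best_k
    k = int(k)
    if n < k:
        raise ValueError(f"need at least k={k} blobs, got {n}")

    if k == 1:
        labels = np.zeros(n, dtype=int)
        centers = z.mean(axis=0, keepdims=True)
    else:
        fit = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS,
                     random_state=seed).fit(z)
        labels, centers = fit.labels_.astype(int), fit.cluster_centers_

    # order groups by descending mean raw localization count
    loc_col = FEATURE_NAMES.index("n_localizations")
    mean_locs = np.array([mat[labels == g, loc_col].mean() for g in range(k)])
    order = np.argsort(-mean_locs, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    labels = relabel[labels]
    centers = centers[order]
    if group_names is None:
        group_names = [f"G{i + 1}" for i in range(k)]
    elif len(group_names) != k:
        raise ValueError("one name per group required")
    return GroupModel(labels, centers, (mean, sd), k, list(group_names), mat)


def match_groups(model_a: GroupModel, model_b: GroupModel,
                 normalize: str = "pooled") -> MatchMatrix:
    """Euclidean distance matrix between the group centers of two models.

    With ``normalize="pooled"`` (default) both collections' raw features are
    z-scored with pooled statistics before computing centers, so the match
    is invariant to any feature-wide affine rescaling applied to both;
    ``normalize="none"`` compares raw-unit centers.
    """
    if model_a.features_raw.shape[1] != model_b.features_raw.shape[1]:
        raise ValueError("mismatched feature registries")
    if normalize == "pooled":
        pooled = np.vstack([model_a.features_raw, model_b.features_raw])
        _, mean, sd = zscore(pooled)
        za, _, _ = zscore(model_a.features_raw, mean, sd)
        zb, _, _ = zscore(model_b.features_raw, mean, sd)
        ca = np.vstack([za[model_a.labels == g].mean(axis=0)
                        for g in range(model_a.k)])
        cb = np.vstack([zb[model_b.labels == g].mean(axis=0)
                        for g in range(model_b.k)])
    elif normalize == "none":
        ca, cb = model_a.centers_raw(), model_b.centers_raw()
    else:
        raise ValueError("normalize must be 'pooled' or 'none'")
    dist = cdist(ca, cb)
    frame = pd.DataFrame(dist, index=model_a.group_names,
                         columns=model_b.group_names)
    best = {col: frame[col].idxmin() for col in frame.columns}
    return MatchMatrix(frame, best)
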