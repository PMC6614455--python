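"""Module-blob matching: are blob sub-modules the building blocks of larger
Cav1 domains?

Every module found by the spectral decomposition is featurized with the same
28-feature descriptor as intact blobs and inherits its parent blob's class.
Modules are pooled per parent class; the class center is the mean feature
vector in a z-scored space pooled over modules and blobs.  The match matrix
reports Euclidean distances between every blob-class center (rows) and
module-class center (columns); the per-column argmin names the blob class
most similar to that class's modules.  On Cav1 domains this read-out shows
the assembly hierarchy: caveolae modules resemble S1B blobs, while S2 and
S1B modules resemble S1A blobs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, features_table
from .groups import MatchMatrix, zscore
from .modularity import _blob_points


def module_features(blobs, decompositions, parent_labels,
                    reference_pt: float = 80.0, weighting: str = "gaussian",
                    blob_ids=None) -> pd.DataFrame:
    """Featurize every module of every blob.

    Parameters
    ----------
    blobs : sequence of point arrays or objects with ``positions``
    decompositions : matching sequence of ModuleDecomposition
    parent_labels : class label per blob, inherited by its modules

    Returns
    -------
    DataFrame with blob_id, module_id, parent_class, n columns followed by
    the 28 features.
    """
    if not (len(blobs) == len(decompositions) == len(parent_labels)):
        raise ValueError("blobs, decompositions and parent_labels must align")
    point_sets, meta = [], []
    for bi, (blob, dec, label) in enumerate(
            zip(blobs, decompositions, parent_labels)):
        pts = _blob_points(blob)
        if len(dec.partition) != len(pts):
            raise ValueError("decomposition does not match blob size")
        for mod in range(dec.n_modules):
            idx = np.flatnonzero(dec.partition == mod)
            if len(idx) == 0:
                raise ValueError("empty module in decomposition")
            point_sets.append(pts[idx])
            meta.append({"blob_id": blob_ids[bi] if blob_ids is not None else bi,
                         "module_id": mod, "parent_class": label,
                         "n": len(idx)})
    feats = features_table(point_sets, reference_pt, weighting=weighting)
    return pd.concat([pd.DataFrame(meta), feats], axis=1)


def _class_centers(z: np.ndarray, labels) -> tuple[list, np.ndarray]:
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    centers = np.vstack([z[labels == c].mean(axis=0) for c in classes])
    return classes, centers


def match_modules_to_blobs(module_feats: pd.DataFrame,
                           blob_feats: pd.DataFrame,
                           module_class_col: str = "parent_class",
                           blob_class_col: str = "class") -> MatchMatrix:
    """Match module classes (columns) against blob classes (rows).

    Both tables must carry the 28 feature columns plus a class column.
    Features are z-scored with statistics pooled over modules and blobs, so
    the argmin per column is invariant to any feature-wide affine rescaling
    applied identically to both.
    """
    for frame, col in ((module_feats, module_class_col),
                       (blob_feats, blob_class_col)):
        missing = set(FEATURE_NAMES) - set(frame.columns)
        if missing or col not in frame.columns:
            raise ValueError("mismatched feature registry or missing class column")
    mod_mat = module_feats[list(FEATURE_NAMES)].to_numpy(dtype=float)
    blob_mat = blob_feats[list(FEATURE_NAMES)].to_numpy(dtype=float)
    pooled = np.vstack([mod_mat, blob_mat])
    _, mean, sd = zscore(pooled)
    zmod, _, _ = zscore(mod_mat, mean, sd)
    zblob, _, _ = zscore(blob_mat, mean, sd)
    mod_classes, mod_centers = _class_centers(zmod, module_feats[module_class_col])
    blob_classes, blob_centers = _class_centers(zblob, blob_feats[blob_class_col])
    dist = np.linalg.norm(blob_centers[:, None, :] - mod_centers[None, :, :],
                          axis=2)
    frame = pd.DataFrame(dist, index=blob_classes, columns=mod_classes)
    best = {col: frame[col].idxmin() for col in frame.columns}
    return MatchMatrix(frame, best)
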