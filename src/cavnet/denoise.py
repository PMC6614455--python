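"""Noise filtering against a random-network reference, and blob segmentation.

A molecular localization is kept when its connectivity in the proximity
network is clearly above what a structureless point set would produce: its
degree at ``pt_denoise`` must reach the chosen percentile of node degrees in
Monte-Carlo uniform point sets of equal count drawn in the same bounding
volume.  Isolated molecules (degree 0, i.e. monomers at the analysis scale)
are always removed.  The retained cloud is then segmented into blobs as the
connected components of the proximity graph at ``pt_segment``, discarding
components below a minimum size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Monte-Carlo replicates of the uniform reference point set
N_REFERENCE_REPLICATES = 99


@dataclass
class NoiseLabeling:
    """Signal/noise decision per molecule plus the null-reference summary."""

    keep: np.ndarray                  # bool per molecule
    reference_stats: dict
    pt_denoise: float

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())


@dataclass
class Blob:
    """A segmented cluster of molecular localizations."""

    blob_id: int
    molecule_indices: np.ndarray      # indices into the retained cloud
    positions: np.ndarray             # (n, 3) nm

    @property
    def n_molecules(self) -> int:
        return len(self.positions)


def _degrees(points: np.ndarray, radius: float) -> np.ndarray:
    n = len(points)
    deg = np.zeros(n, dtype=int)
    if n < 2:
        return deg
    pairs = cKDTree(points).query_pairs(radius, output_type="ndarray")
    if len(pairs):
        deg = np.bincount(pairs.ravel(), minlength=n)
    return deg


def _cloud_points(cloud) -> np.ndarray:
    if hasattr(cloud, "positions"):
        return np.asarray(cloud.positions, dtype=float)
    return np.asarray(cloud, dtype=float)


def denoise(cloud, pt_denoise: float = 80.0, percentile: float = 95.0,
            rng=None, n_replicates: int = N_REFERENCE_REPLICATES) -> NoiseLabeling:
    """Label molecules as signal or noise by a degree-versus-uniform-null test.

    A molecule is kept iff its degree in the ``pt_denoise`` proximity graph
    reaches the ``percentile`` of node degrees pooled over ``n_replicates``
    uniform random point sets of equal count in the data's bounding box, and
    its degree is at least 1.
    """
    if not pt_denoise > 0:
        raise ValueError("pt_denoise must be positive")
    if not 50.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (50, 100)")
    points = _cloud_points(cloud)
    n = len(points)
    if n == 0:
        return NoiseLabeling(np.zeros(0, dtype=bool),
                             {"threshold": 0.0, "n_replicates": 0}, pt_denoise)
    lo, hi = points.min(axis=0), points.max(axis=0)
    if np.allclose(lo, hi):
        raise ValueError("degenerate bounding volume: all points coincident")
    rng = np.random.default_rng(rng)

    deg = _degrees(points, pt_denoise)
    null_degrees = np.concatenate([
        _degrees(lo + rng.uniform(size=(n, 3)) * (hi - lo), pt_denoise)
        for _ in range(n_replicates)
    ])
    threshold = float(np.percentile(null_degrees, percentile))
    keep = (deg >= threshold) & (deg >= 1)
    stats = {
        "threshold": threshold,
        "percentile": percentile,
        "n_replicates": n_replicates,
        "null_degree_mean": float(null_degrees.mean()),
        "null_degree_max": int(null_degrees.max()),
        "data_degree_mean": float(deg.mean()),
    }
    logger.info("denoise: kept %d / %d molecules (degree threshold %.1f at "
                "%.0fth percentile, pt %.0f nm)", keep.sum(), n, threshold,
                percentile, pt_denoise)
    return NoiseLabeling(keep, stats, pt_denoise)


def segment(retained, pt_segment: float = 200.0,
            min_blob_size: int = 5) -> list[Blob]:
    """Segment a molecule cloud into blobs (proximity-graph components).

    Components with fewer than ``min_blob_size`` molecules are discarded
    (their count is logged).  Returned blob ids are contiguous and ordered
    by the smallest molecule index in each blob, which makes the output
    invariant to rigid motion and stable under input ordering.
    """
    if not pt_segment > 0:
        raise ValueError("pt_segment must be positive")
    if min_blob_size < 1:
        raise ValueError("min_blob_size must be >= 1")
    points = _cloud_points(retained)
    n = len(points)
    if n == 0:
        return []
    pairs = cKDTree(points).query_pairs(pt_segment, output_type="ndarray")
    graph = csr_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                       shape=(n, n)) if len(pairs) else csr_matrix((n, n))
    n_comp, comp = connected_components(graph, directed=False)
    blobs, discarded = [], 0
    comps = sorted((np.flatnonzero(comp == c) for c in range(n_comp)),
                   key=lambda idx: idx[0])
    for idx in comps:
        if len(idx) < min_blob_size:
            discarded += 1
            continue
        blobs.append(Blob(len(blobs), idx, points[idx]))
    logger.info("segment: %d blobs at pt %.0f nm (%d components below "
                "size %d discarded)", len(blobs), pt_segment, discarded,
                min_blob_size)
    return blobs
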