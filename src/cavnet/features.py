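"""The 28-dimensional descriptor of a point set (blob or module).

The descriptor covers counts and blink statistics, extent and shape
(ranges, radius of gyration, pairwise distances, PCA shape ratios,
covariance-ellipsoid volume), hollowness (shell-like versus filled), and
network statistics of the proximity graph at a reference proximity
threshold (density, degree statistics, clustering, characteristic path,
diameter, components, spectral modularity, assortativity, edge length).

All features are invariant under rigid translation; the axis-aligned
ranges and bounding-box volume (slots 4-7) are the only rotation-variant
entries.  Degenerate point sets (one or two points) get defined values:
graph statistics are 0 and the component/module counts follow the trivial
graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from scipy.spatial.distance import pdist

from .modularity import (DEFAULT_DECAY_NM, ProximityGraph, build_graph,
                         decompose_blob)

#: canonical feature registry, version 1 — order is part of the contract
FEATURE_NAMES = (
    "n_localizations",          # 1
    "total_blinks",             # 2
    "mean_blinks_per_molecule",  # 3
    "x_range",                  # 4
    "y_range",                  # 5
    "z_range",                  # 6
    "bounding_box_volume",      # 7
    "radius_of_gyration",       # 8
    "mean_pairwise_distance",   # 9
    "median_pairwise_distance",  # 10
    "max_pairwise_distance",    # 11
    "hollowness",               # 12
    "linearity",                # 13
    "planarity",                # 14
    "sphericity",               # 15
    "ellipsoid_volume",         # 16
    "network_density",          # 17
    "mean_degree",              # 18
    "degree_variance",          # 19
    "clustering_coefficient",   # 20
    "characteristic_path",      # 21
    "graph_diameter",           # 22
    "n_connected_components",   # 23
    "modularity",               # 24
    "n_modules",                # 25
    "mean_module_size",         # 26
    "degree_assortativity",     # 27
    "mean_edge_length",         # 28
)

FEATURE_REGISTRY_VERSION = "1"

#: features named in group-matching read-outs; guaranteed present
NAMED_FEATURES = ("n_localizations", "hollowness", "characteristic_path",
                  "modularity", "x_range", "network_density")


@dataclass
class BlobFeatures:
    """Ordered 28-feature vector for one point set."""

    values: np.ndarray
    reference_pt: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"feature vector must have length {len(FEATURE_NAMES)}")

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES))


def hollowness(points) -> float:
    """Shell-likeness: (centroid-to-nearest-point distance) / (mean radial
    distance from the centroid).

    Close to 1 for points on a hollow shell, much smaller for filled sets;
    defined as 0 for fewer than 4 points.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 4:
        return 0.0
    radial = np.linalg.norm(points - points.mean(axis=0), axis=1)
    mean_radial = radial.mean()
    if mean_radial == 0:
        return 0.0
    return float(radial.min() / mean_radial)


def _as_nx(graph) -> nx.Graph:
    if isinstance(graph, ProximityGraph):
        return graph.to_networkx()
    return graph


def network_density(graph) -> float:
    """2|E| / (n (n-1)); 0 for a single node."""
    g = _as_nx(graph)
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def characteristic_path(graph) -> float:
    """Mean shortest-path hop count over all connected node pairs.

    Disconnected pairs are excluded; a graph with no edges has
    characteristic path 0 by convention.
    """
    g = _as_nx(graph)
    n = g.number_of_nodes()
    if n < 2 or g.number_of_edges() == 0:
        return 0.0
    hops = _hop_matrix(g)
    finite = np.isfinite(hops) & (hops > 0)
    if not finite.any():
        return 0.0
    return float(hops[finite].mean())


def _hop_matrix(g: nx.Graph) -> np.ndarray:
    adj = nx.to_scipy_sparse_array(g, weight=None, format="csr")
    return shortest_path(csr_matrix(adj), method="D", unweighted=True)


def _shape_ratios(points: np.ndarray) -> tuple[float, float, float, float]:
    """(linearity, planarity, sphericity, ellipsoid volume) from the
    covariance eigenvalues l1 >= l2 >= l3:

    linearity (l1-l2)/l1, planarity (l2-l3)/l1, sphericity l3/l1 (the three
    sum to 1), and the volume of the uniform ellipsoid with matching
    covariance (semi-axes sqrt(5 l_i)).
    """
    if len(points) < 2:
        return 0.0, 0.0, 0.0, 0.0
    cov = np.cov(points.T)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    if eig[0] <= 0:
        return 0.0, 0.0, 0.0, 0.0
    lin = (eig[0] - eig[1]) / eig[0]
    pla = (eig[1] - eig[2]) / eig[0]
    sph = eig[2] / eig[0]
    volume = 4.0 / 3.0 * np.pi * float(np.prod(np.sqrt(5.0 * eig)))
    return float(lin), float(pla), float(sph), volume


def compute_features(points, reference_pt: float = 80.0, blink_counts=None,
                     weighting: str = "gaussian",
                     decay: float = DEFAULT_DECAY_NM) -> BlobFeatures:
    """Compute the 28-feature descriptor of a point set.

    Graph features are computed on the proximity network at ``reference_pt``
    (nm); the modularity block uses the spectral decomposition with the
    given edge weighting.  ``blink_counts`` (one per point) default to 1.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) == 0:
        raise ValueError("expected a non-empty (n, 3) point array")
    n = len(points)
    blink_counts = (np.ones(n) if blink_counts is None
                    else np.asarray(blink_counts, dtype=float))

    ranges = np.ptp(points, axis=0) if n > 1 else np.zeros(3)
    centroid = points.mean(axis=0)
    rg = float(np.sqrt(((points - centroid) ** 2).sum(axis=1).mean()))
    dists = pdist(points) if n > 1 else np.zeros(1)
    lin, pla, sph, ell_vol = _shape_ratios(points)

    graph = build_graph(points, reference_pt, weighting, decay)
    g = graph.to_networkx()
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    n_edges = g.number_of_edges()
    if n_edges:
        hops = _hop_matrix(g)
        finite = np.isfinite(hops) & (hops > 0)
        char_path = float(hops[finite].mean()) if finite.any() else 0.0
        comp_sizes = [len(c) for c in nx.connected_components(g)]
        largest = max(nx.connected_components(g), key=len)
        sub_hops = hops[np.ix_(sorted(largest), sorted(largest))]
        diameter = float(sub_hops[np.isfinite(sub_hops)].max())
        clustering = float(nx.transitivity(g))
        try:
            # regular graphs have zero degree variance; define assortativity 0
            with np.errstate(invalid="ignore", divide="ignore"), \
                 warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                assort = nx.degree_assortativity_coefficient(g)
            assort = 0.0 if not np.isfinite(assort) else float(assort)
        except (ZeroDivisionError, ValueError):
            assort = 0.0
        a, b = np.nonzero(np.triu(graph.adjacency))
        mean_edge_len = float(np.linalg.norm(points[a] - points[b],
                                             axis=1).mean())
    else:
        char_path = diameter = clustering = assort = mean_edge_len = 0.0
    n_components = nx.number_connected_components(g)

    dec = decompose_blob(points, reference_pt, weighting, decay)
    values = np.array([
        float(n),
        float(blink_counts.sum()),
        float(blink_counts.mean()),
        float(ranges[0]), float(ranges[1]), float(ranges[2]),
        float(np.prod(ranges)),
        rg,
        float(dists.mean()) if n > 1 else 0.0,
        float(np.median(dists)) if n > 1 else 0.0,
        float(dists.max()) if n > 1 else 0.0,
        hollowness(points),
        lin, pla, sph, ell_vol,
        network_density(g),
        float(degrees.mean()) if n else 0.0,
        float(degrees.var()) if n else 0.0,
        clustering,
        char_path,
        diameter,
        float(n_components),
        dec.q,
        float(dec.n_modules),
        float(n / dec.n_modules) if dec.n_modules else 0.0,
        assort,
        mean_edge_len,
    ])
    return BlobFeatures(values, reference_pt)


def features_table(point_sets, reference_pt: float = 80.0,
                   blink_counts=None, weighting: str = "gaussian",
                   decay: float = DEFAULT_DECAY_NM, ids=None) -> pd.DataFrame:
    """Featurize a list of point sets into a DataFrame (one row each)."""
    rows = []
    for i, pts in enumerate(point_sets):
        bc = None if blink_counts is None else blink_counts[i]
        rows.append(compute_features(pts, reference_pt, bc, weighting,
                                     decay).values)
    frame = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    if ids is not None:
        frame.insert(0, "id", list(ids))
    return frame


def feature_registry() -> dict:
    """Machine-readable registry of the descriptor (emitted with outputs)."""
    return {"version": FEATURE_REGISTRY_VERSION,
            "n_features": len(FEATURE_NAMES),
            "names": list(FEATURE_NAMES),
            "named_subset": list(NAMED_FEATURES)}
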