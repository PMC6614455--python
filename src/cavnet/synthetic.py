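"""Synthetic ground-truth generator for caveolin-1 domain point clouds.

Caveolin-1 (Cav1) assembles at the plasma membrane into four structural
classes resolvable by 3D single-molecule localization microscopy (SMLM):

* ``S1A`` — the smallest scaffold, a stack of two small polygonal rings of
  5–6 molecules each (~10–12 molecules, < 20 nm across), matching the 8S
  Cav1 homo-oligomer.
* ``S1B`` — a dimer of two S1A units.
* ``S2``  — a hemispherical scaffold of five molecular sub-clusters of ~14
  molecules on a ~40 nm radius cap.
* ``CAV`` — a caveola: a hollow spherical coat of ~145 molecules organised
  into seven sub-clusters on a ~40 nm radius shell.

Each generated blob carries planted sub-module labels so that module
recovery by downstream network analysis can be scored against ground truth.
SMLM acquisition is emulated by drawing one or more "blinks" per molecule
(fluorophore re-activations) with anisotropic Gaussian localization error
(~10 nm lateral, ~30 nm axial) plus homogeneous background noise, which is
what the merging and denoising stages must undo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import write_localizations

CLASS_LABELS = ("S1A", "S1B", "S2", "CAV")

#: truth_map blob/molecule id used for background noise events
NOISE = -1

# Per-class geometry defaults (nm).  Totals follow the printed compositions:
# CAV ~145 molecules in 7 sub-clusters, S2 5x14 on a hemisphere, S1B = two
# S1A units, S1A = 2 polygonal rings of 5-6 molecules.
#
# S2 and CAV sub-clusters default to *structured* sub-units implementing the
# assembly hierarchy (S2 built from S1A-like double rings, caveolae from
# S1B-like dimers); ``subunit_style="gaussian"`` plants isotropic Gaussian
# clusters of the same sizes instead.
GEOMETRY_DEFAULTS = {
    "S1A": dict(ring_radius=6.0, ring_separation=12.0, ring_sizes=(5, 6),
                jitter=1.0),
    "S1B": dict(unit_separation=16.0),
    "S2": dict(radius=40.0, n_subclusters=5, molecules_per_subcluster=14,
               subunit_style="structured", cluster_sigma=5.0,
               angular_jitter=0.05),
    "CAV": dict(radius=40.0, n_subclusters=7, n_molecules=145,
                subunit_style="structured", shell_thickness=20.0,
                cluster_sigma=5.0, angular_jitter=0.05),
}


@dataclass
class GroundTruthBlob:
    """A noiseless molecular model of one Cav1 domain."""

    class_label: str
    molecule_positions: np.ndarray      # (n, 3) nm
    submodule_labels: np.ndarray        # (n,) planted module id
    center: np.ndarray                  # (3,) nm

    def __post_init__(self):
        self.molecule_positions = np.asarray(self.molecule_positions, dtype=float)
        self.submodule_labels = np.asarray(self.submodule_labels, dtype=int)
        self.center = np.asarray(self.center, dtype=float)
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.class_label!r}")
        if len(self.molecule_positions) < 1:
            raise ValueError("a blob needs at least one molecule")
        if len(self.submodule_labels) != len(self.molecule_positions):
            raise ValueError("one submodule label per molecule required")
        if not np.isfinite(self.molecule_positions).all():
            raise ValueError("non-finite molecule coordinates")

    @property
    def n_molecules(self) -> int:
        return len(self.molecule_positions)

    def translated(self, offset) -> "GroundTruthBlob":
        offset = np.asarray(offset, dtype=float)
        return GroundTruthBlob(self.class_label,
                               self.molecule_positions + offset,
                               self.submodule_labels.copy(),
                               self.center + offset)


@dataclass
class BlinkModel:
    """Photophysics + localization-error model for blink simulation.

    blinks_per_molecule_mean : mean blink multiplicity (>= 1); counts are
        drawn as 1 + Poisson(mean - 1) so every molecule blinks at least once.
    lateral_sigma, axial_sigma : localization error (nm) in x/y and z.
    noise_density : homogeneous background events per µm³ of field of view.
    """

    blinks_per_molecule_mean: float = 4.0
    lateral_sigma: float = 10.0
    axial_sigma: float = 30.0
    noise_density: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.blinks_per_molecule_mean < 1:
            raise ValueError("blinks_per_molecule_mean must be >= 1")
        if self.lateral_sigma < 0 or self.axial_sigma < 0:
            raise ValueError("localization sigmas must be >= 0")
        if self.noise_density < 0:
            raise ValueError("noise_density must be >= 0")


@dataclass
class SyntheticScene:
    """Blink table plus complete ground truth for one simulated field of view."""

    blobs: list
    blinks: pd.DataFrame                # x, y, z, frame
    truth: pd.DataFrame                 # blob_id, molecule_id per blink (NOISE for bg)
    fov: tuple                          # (x, y, z) extents in nm

    def write(self, csv_path: str | Path, truth_path: str | Path | None = None,
              comment: str | None = None) -> None:
        write_localizations(self.blinks, csv_path, header_comment=comment)
        if truth_path is not None:
            payload = {
                "fov_nm": list(self.fov),
                "blobs": [
                    {"blob_id": i, "class_label": b.class_label,
                     "n_molecules": int(b.n_molecules),
                     "center_nm": b.center.tolist(),
                     "submodule_labels": b.submodule_labels.tolist()}
                    for i, b in enumerate(self.blobs)
                ],
                "blink_truth": {
                    "blob_id": self.truth["blob_id"].tolist(),
                    "molecule_id": self.truth["molecule_id"].tolist(),
                },
            }
            Path(truth_path).write_text(json.dumps(payload), encoding="utf-8")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly spaced unit directions on the sphere."""
    i = np.arange(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = golden * i
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def hemisphere_directions(n: int, ring_polar_deg: float = 75.0) -> np.ndarray:
    """One polar direction plus (n-1) evenly spaced directions on a ring."""
    dirs = [np.array([0.0, 0.0, 1.0])]
    polar = np.deg2rad(ring_polar_deg)
    for j in range(n - 1):
        az = 2.0 * np.pi * j / max(n - 1, 1)
        dirs.append(np.array([np.sin(polar) * np.cos(az),
                              np.sin(polar) * np.sin(az),
                              np.cos(polar)]))
    return np.asarray(dirs)


def _jitter_directions(dirs: np.ndarray, angular_jitter: float,
                       rng: np.random.Generator) -> np.ndarray:
    if angular_jitter <= 0:
        return dirs
    out = dirs + rng.normal(scale=angular_jitter, size=dirs.shape)
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _s1a_points(rng: np.random.Generator, ring_radius: float,
                ring_separation: float, ring_sizes, jitter: float,
                fixed_sizes=None):
    """Two stacked polygonal rings; each ring is one planted sub-module.

    Ring sizes are drawn uniformly from ``ring_sizes`` (inclusive bounds)
    unless ``fixed_sizes`` gives them explicitly.
    """
    pts, labels = [], []
    for ring in range(2):
        if fixed_sizes is not None:
            size = int(fixed_sizes[ring])
        else:
            size = int(rng.integers(ring_sizes[0], ring_sizes[1] + 1))
        z = (ring - 0.5) * ring_separation
        phase = rng.uniform(0, 2 * np.pi)
        for i in range(size):
            theta = 2 * np.pi * i / size + phase
            p = np.array([ring_radius * np.cos(theta),
                          ring_radius * np.sin(theta), z])
            pts.append(p + rng.normal(scale=jitter, size=3))
            labels.append(ring)
    return np.asarray(pts), np.asarray(labels, dtype=int)


def _split_evenly(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + 1] * extra + [base] * (parts - extra)


def _s1a_unit(rng: np.random.Generator, n_molecules: int) -> np.ndarray:
    """A randomly oriented S1A-like double ring with exactly n molecules."""
    g = GEOMETRY_DEFAULTS["S1A"]
    sizes = _split_evenly(n_molecules, 2)
    pts, _ = _s1a_points(rng, g["ring_radius"], g["ring_separation"],
                         g["ring_sizes"], g["jitter"], fixed_sizes=sizes)
    return pts @ _random_rotation(rng).T


def _s1b_unit(rng: np.random.Generator, n_molecules: int,
              separation: float | None = None) -> np.ndarray:
    """A randomly oriented S1B-like dimer of two S1A-like units."""
    if separation is None:
        separation = GEOMETRY_DEFAULTS["S1B"]["unit_separation"]
    axis = _unit(rng.normal(size=3))
    na, nb = _split_evenly(n_molecules, 2)
    return np.vstack([_s1a_unit(rng, na) - 0.5 * separation * axis,
                      _s1a_unit(rng, nb) + 0.5 * separation * axis])


def generate_blob(class_label: str, rng: np.random.Generator | int | None = None,
                  center=(0.0, 0.0, 0.0), **geometry) -> GroundTruthBlob:
    """Generate one ground-truth blob of the requested structural class.

    Geometry keywords override the per-class defaults in
    :data:`GEOMETRY_DEFAULTS` (radii, sub-cluster counts, molecules per
    sub-cluster, spreads).  Sub-clusters are placed at evenly spaced
    directions on the shell/hemisphere with a small angular jitter; each
    sub-cluster is one planted module.
    """
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class label {class_label!r}; "
                         f"expected one of {CLASS_LABELS}")
    rng = np.random.default_rng(rng)
    params = dict(GEOMETRY_DEFAULTS[class_label])
    unknown = set(geometry) - set(params)
    if unknown:
        raise ValueError(f"unknown geometry parameters for {class_label}: {unknown}")
    params.update(geometry)
    center = np.asarray(center, dtype=float)

    if class_label == "S1A":
        if params["ring_radius"] <= 0:
            raise ValueError("ring_radius must be positive")
        pts, labels = _s1a_points(rng, params["ring_radius"],
                                  params["ring_separation"],
                                  params["ring_sizes"], params["jitter"])
        pts = pts @ _random_rotation(rng).T

    elif class_label == "S1B":
        # dimer of two independently generated S1A units
        axis = _unit(rng.normal(size=3))
        half = 0.5 * params["unit_separation"] * axis
        unit_a = generate_blob("S1A", rng)
        unit_b = generate_blob("S1A", rng)
        pts = np.vstack([unit_a.molecule_positions - half,
                         unit_b.molecule_positions + half])
        labels = np.concatenate([unit_a.submodule_labels,
                                 unit_b.submodule_labels + 2])

    elif class_label == "S2":
        radius = params["radius"]
        if radius <= 0:
            raise ValueError("radius must be positive")
        dirs = hemisphere_directions(params["n_subclusters"])
        dirs = _jitter_directions(dirs, params["angular_jitter"], rng)
        m = params["molecules_per_subcluster"]
        pts, labels = [], []
        for c, d in enumerate(dirs):
            if params["subunit_style"] == "structured":
                pts.append(_s1a_unit(rng, m) + d * radius)
            else:
                pts.append(d * radius +
                           rng.normal(scale=params["cluster_sigma"],
                                      size=(m, 3)))
            labels.extend([c] * m)
        pts = np.vstack(pts)
        labels = np.asarray(labels, dtype=int)

    else:  # CAV
        radius = params["radius"]
        if radius <= 0:
            raise ValueError("radius must be positive")
        k = params["n_subclusters"]
        sizes = _split_evenly(params["n_molecules"], k)
        dirs = fibonacci_sphere(k) @ _random_rotation(rng).T
        dirs = _jitter_directions(dirs, params["angular_jitter"], rng)
        half_t = 0.5 * params["shell_thickness"]
        pts, labels = [], []
        for c, (d, m) in enumerate(zip(dirs, sizes)):
            if params["subunit_style"] == "structured":
                pts.append(_s1b_unit(rng, m) + d * radius)
            else:
                tangential = d * radius + rng.normal(
                    scale=params["cluster_sigma"], size=(m, 3))
                u = tangential / np.linalg.norm(tangential, axis=1,
                                                keepdims=True)
                radial = radius + rng.uniform(-half_t, half_t, size=m)
                pts.append(u * radial[:, None])
            labels.extend([c] * m)
        pts = np.vstack(pts)
        labels = np.asarray(labels, dtype=int)

    return GroundTruthBlob(class_label, pts + center, labels, center)


def simulate_blinks(blobs: Sequence[GroundTruthBlob], blink_model: BlinkModel,
                    fov: tuple | None = None,
                    rng: np.random.Generator | None = None,
                    n_frames: int = 10000) -> SyntheticScene:
    """Simulate SMLM blink localizations from ground-truth blobs.

    Every molecule emits ``1 + Poisson(mean - 1)`` blinks scattered around
    its true position with anisotropic Gaussian error; uniform background
    events are added at ``noise_density`` per µm³ of the field of view.
    The returned scene's ``truth`` table maps every blink to its source
    (blob id, molecule id), with :data:`NOISE` for background.
    """
    if len(blobs) == 0:
        raise ValueError("simulate_blinks requires at least one blob")
    if rng is None:
        rng = np.random.default_rng(blink_model.seed)

    all_pos = np.vstack([b.molecule_positions for b in blobs])
    if fov is None:
        pad = 200.0
        lo = all_pos.min(axis=0) - pad
        extent = np.ptp(all_pos, axis=0) + 2 * pad
    else:
        lo = np.zeros(3)
        extent = np.asarray(fov, dtype=float)

    sigma = np.array([blink_model.lateral_sigma, blink_model.lateral_sigma,
                      blink_model.axial_sigma])
    xyz, blob_ids, mol_ids = [], [], []
    mol_counter = 0
    for bi, blob in enumerate(blobs):
        for pos in blob.molecule_positions:
            n_bl = 1 + rng.poisson(blink_model.blinks_per_molecule_mean - 1.0)
            xyz.append(pos + rng.normal(size=(n_bl, 3)) * sigma)
            blob_ids.extend([bi] * n_bl)
            mol_ids.extend([mol_counter] * n_bl)
            mol_counter += 1
    xyz = np.vstack(xyz)

    volume_um3 = float(np.prod(extent)) / 1e9
    n_noise = rng.poisson(blink_model.noise_density * volume_um3)
    if n_noise:
        noise = lo + rng.uniform(size=(n_noise, 3)) * extent
        xyz = np.vstack([xyz, noise])
        blob_ids.extend([NOISE] * n_noise)
        mol_ids.extend([NOISE] * n_noise)

    # keep every blink inside the field of view
    xyz = np.clip(xyz, lo, lo + extent)
    frames = rng.integers(0, n_frames, size=len(xyz))
    order = np.argsort(frames, kind="stable")
    blinks = pd.DataFrame({"x": xyz[order, 0], "y": xyz[order, 1],
                           "z": xyz[order, 2], "frame": frames[order]})
    truth = pd.DataFrame({"blob_id": np.asarray(blob_ids)[order],
                          "molecule_id": np.asarray(mol_ids)[order]})
    return SyntheticScene(list(blobs), blinks.reset_index(drop=True),
                          truth.reset_index(drop=True), tuple(extent))


#: conservative bound on blob extent from center, used for scene placement
_BLOB_RADIUS_BOUND = 70.0


def generate_scene(class_counts: Mapping[str, int],
                   fov: tuple = (5000.0, 5000.0, 1000.0),
                   blink_model: BlinkModel | None = None,
                   seed: int = 0,
                   min_separation: float = 500.0) -> SyntheticScene:
    """Generate a full synthetic field of view with well-separated blobs.

    Blob centers are placed on a shuffled grid whose spacing guarantees a
    minimum inter-blob molecule separation of ``min_separation`` nm, which
    should exceed the largest proximity threshold used downstream so that
    segmentation is well-posed.
    """
    if blink_model is None:
        blink_model = BlinkModel(seed=seed)
    for label, count in class_counts.items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        if count < 0:
            raise ValueError("class counts must be non-negative")
    fov = tuple(float(v) for v in fov)
    if min(fov) <= 0:
        raise ValueError("fov extents must be positive")

    ss = np.random.SeedSequence(seed)
    rng_place, rng_blink, *_ = [np.random.default_rng(s) for s in ss.spawn(3)]

    n_total = sum(class_counts.get(c, 0) for c in CLASS_LABELS)
    if n_total == 0:
        blinks = pd.DataFrame({"x": [], "y": [], "z": [], "frame": []}).astype(
            {"x": float, "y": float, "z": float, "frame": int})
        truth = pd.DataFrame({"blob_id": pd.Series(dtype=int),
                              "molecule_id": pd.Series(dtype=int)})
        return SyntheticScene([], blinks, truth, fov)

    spacing = min_separation + 2 * _BLOB_RADIUS_BOUND
    margin = _BLOB_RADIUS_BOUND + 30.0
    xs = np.arange(margin, fov[0] - margin + 1e-9, spacing)
    ys = np.arange(margin, fov[1] - margin + 1e-9, spacing)
    z0 = fov[2] / 2.0
    sites = np.array([(x, y, z0) for x in xs for y in ys])
    if len(sites) < n_total:
        raise ValueError(
            f"fov {fov} too small for {n_total} blobs at "
            f"min_separation {min_separation} nm ({len(sites)} sites)")
    rng_place.shuffle(sites)

    labels = [c for c in CLASS_LABELS for _ in range(class_counts.get(c, 0))]
    blob_streams = np.random.SeedSequence((seed, 7)).spawn(n_total)
    blobs = [generate_blob(label, np.random.default_rng(stream), center=site)
             for label, site, stream in zip(labels, sites, blob_streams)]
    return simulate_blinks(blobs, blink_model, fov=fov, rng=rng_blink)
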