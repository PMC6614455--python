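"""Pipeline orchestration: simulate/merge/denoise/segment/features/groups/
modules/match with CSV outputs and a run manifest.

The stage sequence mirrors how an SMLM field of view is analysed: raw blinks
are merged into molecules at the MPT, noise is filtered, the retained cloud
is segmented into blobs, every blob gets its 28-feature descriptor, blobs
are grouped by unsupervised clustering, each blob is decomposed into modules
at the module PT, modules are featurized, and module classes are matched
against blob classes.  A fixed seed makes the whole run bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .denoise import denoise, segment
from .features import feature_registry, features_table
from .groups import learn_groups, match_groups
from .io import read_localizations, write_localizations
from .merge import iterative_merge
from .modularity import decompose_blob, multi_pt_analysis
from .module_matching import match_modules_to_blobs, module_features

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run (distances in nm)."""

    mpt: float = 19.0
    mpt_sweep: tuple = ()
    pt_grid: tuple = tuple(float(pt) for pt in range(10, 251, 10))
    stable_range: tuple = (60.0, 170.0)
    weighting: str = "gaussian"
    similarity_decay: float = 25.0
    pt_denoise: float = 80.0
    denoise_percentile: float = 95.0
    pt_segment: float = 200.0
    min_blob_size: int = 5
    reference_pt: float = 80.0
    module_pt: float = 80.0
    k: int | str = 4
    seed: int = 0
    units: str = "nm"

    def validate(self) -> None:
        for name in ("mpt", "pt_denoise", "pt_segment", "reference_pt",
                     "module_pt"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if any(pt <= 0 for pt in self.pt_grid):
            raise ValueError("pt_grid thresholds must be positive")
        lo, hi = self.stable_range
        if not (min(self.pt_grid) <= lo < hi <= max(self.pt_grid)):
            raise ValueError("stable_range must lie within the pt_grid span")
        if not 50.0 < self.denoise_percentile < 100.0:
            raise ValueError("denoise_percentile must lie in (50, 100)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("mpt_sweep", "pt_grid", "stable_range"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("mpt_sweep", "pt_grid", "stable_range"):
            d[key] = list(d[key])
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, blinks=None, input_path=None,
                 outdir="cavnet_out") -> dict:
    """Run the full analysis and write all output tables plus a manifest.

    Either a blink table (DataFrame) or an ``input_path`` CSV must be given.
    Returns a result bundle dict with the in-memory objects and the manifest.
    On a stage failure the partial outputs are retained, a FAILED marker is
    written, and :class:`StageError` is raised naming the stage.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"cavnet_version": __version__, "seed": config.seed,
                "config": config.to_dict(), "counts": {}, "stages": []}
    bundle = {"manifest": manifest, "outdir": outdir}
    comment = f"cavnet {__version__} seed={config.seed}"
    stage = "read"

    def finish_stage(name, **counts):
        manifest["stages"].append(name)
        manifest["counts"].update(counts)

    try:
        if blinks is None:
            if input_path is None:
                raise ValueError("either blinks or input_path is required")
            blinks = read_localizations(input_path, units=config.units)
        finish_stage("read", n_blinks=int(len(blinks)))

        stage = "merge"
        cloud = iterative_merge(blinks, config.mpt)
        bundle["molecules"] = cloud
        molecules = cloud.to_frame()
        write_localizations(molecules, outdir / "molecules.csv", comment)
        finish_stage("merge", n_molecules=cloud.n_molecules)

        stage = "denoise"
        if cloud.n_molecules == 0:
            labeling = None
            retained = cloud.positions
            retained_counts = cloud.blink_count
        else:
            labeling = denoise(cloud, config.pt_denoise,
                               config.denoise_percentile,
                               rng=np.random.default_rng(config.seed))
            retained = cloud.positions[labeling.keep]
            retained_counts = cloud.blink_count[labeling.keep]
        bundle["noise_labeling"] = labeling
        finish_stage("denoise", n_retained=int(len(retained)))

        stage = "segment"
        blobs = segment(retained, config.pt_segment, config.min_blob_size)
        bundle["blobs"] = blobs
        assignment = np.full(len(retained), -1, dtype=int)
        for blob in blobs:
            assignment[blob.molecule_indices] = blob.blob_id
        retained_frame = pd.DataFrame({
            "x": retained[:, 0], "y": retained[:, 1], "z": retained[:, 2],
            "blink_count": retained_counts, "blob_id": assignment})
        write_localizations(retained_frame, outdir / "blobs.csv", comment)
        finish_stage("segment", n_blobs=len(blobs),
                     n_in_blobs=int(sum(b.n_molecules for b in blobs)))

        stage = "features"
        (outdir / "feature_registry.json").write_text(
            json.dumps(feature_registry()), encoding="utf-8")
        if blobs:
            blob_counts = [retained_counts[b.molecule_indices] for b in blobs]
            blob_feats = features_table(
                [b.positions for b in blobs], config.reference_pt,
                blink_counts=blob_counts, weighting=config.weighting,
                decay=config.similarity_decay,
                ids=[b.blob_id for b in blobs])
        else:
            blob_feats = features_table([], config.reference_pt)
        bundle["blob_features"] = blob_feats
        write_localizations(blob_feats, outdir / "blob_features.csv", comment)
        finish_stage("features", n_featurized=len(blob_feats))

        stage = "groups"
        k = config.k
        if blobs and (k == "auto" or int(k) <= len(blobs)):
            model = learn_groups(blob_feats.drop(columns=["id"]), k=k,
                                 seed=config.seed)
            groups_frame = model.to_frame(ids=blob_feats["id"])
            class_of_blob = [model.group_names[g] for g in model.labels]
        else:
            model, class_of_blob = None, []
            groups_frame = pd.DataFrame({"id": [], "group": [],
                                         "group_name": []})
        bundle["group_model"] = model
        write_localizations(groups_frame, outdir / "groups.csv", comment)
        finish_stage("groups", n_groups=model.k if model else 0)

        stage = "modules"
        curves, decomps, module_rows = [], [], []
        for blob in blobs:
            curve = multi_pt_analysis(blob.positions, list(config.pt_grid),
                                      config.weighting,
                                      config.similarity_decay)
            curve.insert(0, "blob_id", blob.blob_id)
            curves.append(curve)
            dec = decompose_blob(blob.positions, config.module_pt,
                                 config.weighting, config.similarity_decay)
            decomps.append(dec)
            for mod in range(dec.n_modules):
                for mol in np.flatnonzero(dec.partition == mod):
                    module_rows.append((blob.blob_id, config.module_pt, mod,
                                        int(blob.molecule_indices[mol])))
        bundle["decompositions"] = decomps
        curves_frame = (pd.concat(curves, ignore_index=True) if curves
                        else pd.DataFrame())
        write_localizations(curves_frame, outdir / "curves.csv", comment)
        modules_frame = pd.DataFrame(
            module_rows, columns=["blob_id", "pt", "module_id", "molecule_id"])
        write_localizations(modules_frame, outdir / "modules.csv", comment)
        finish_stage("modules",
                     n_modules=int(sum(d.n_modules for d in decomps)))

        stage = "match"
        if blobs and model is not None:
            mod_feats = module_features(blobs, decomps, class_of_blob,
                                        config.reference_pt, config.weighting,
                                        blob_ids=[b.blob_id for b in blobs])
            blob_feats_cls = blob_feats.drop(columns=["id"]).copy()
            blob_feats_cls["class"] = class_of_blob
            match = match_modules_to_blobs(mod_feats, blob_feats_cls)
            write_localizations(mod_feats, outdir / "module_features.csv",
                                comment)
            match.distances.to_csv(outdir / "module_blob_match.csv")
            bundle["module_features"] = mod_feats
            bundle["module_blob_match"] = match
            self_match = match_groups(model, model)
            self_match.distances.to_csv(outdir / "group_match.csv")
            bundle["group_match"] = self_match
        finish_stage("match")

        manifest["status"] = "ok"
    except Exception as exc:  # noqa: BLE001 - abort naming the stage
        manifest["status"] = "FAILED"
        manifest["failed_stage"] = stage
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n", encoding="utf-8")
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
        raise StageError(stage, exc) from exc

    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    logger.info("pipeline complete: %s", manifest["counts"])
    return bundle
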