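"""Ground-truth generator contracts: class compositions, blink simulation
statistics, scene placement and serialization round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from cavnet import read_localizations
from cavnet.synthetic import (BlinkModel, CLASS_LABELS, GroundTruthBlob,
                              NOISE, generate_blob, generate_scene,
                              simulate_blinks)


class TestGenerateBlob:
    @pytest.mark.parametrize("cls, n_lo, n_hi, n_submodules", [
        ("S1A", 10, 12, 2),    # two polygonal rings of 5-6 molecules
        ("S1B", 20, 24, 4),    # dimer of two S1A units
        ("S2", 70, 70, 5),     # hemisphere of five 14-molecule sub-units
        ("CAV", 145, 145, 7),  # hollow shell of seven ~21-molecule sub-units
    ])
    def test_class_compositions(self, cls, n_lo, n_hi, n_submodules):
        for seed in range(5):
            blob = generate_blob(cls, seed)
            assert n_lo <= blob.n_molecules <= n_hi
            assert len(set(blob.submodule_labels.tolist())) == n_submodules
            assert len(blob.submodule_labels) == blob.n_molecules
            assert np.isfinite(blob.molecule_positions).all()

    def test_s1a_example_composition(self):
        blob = generate_blob("S1A", 1)
        assert 10 <= blob.n_molecules <= 12
        assert set(blob.submodule_labels.tolist()) == {0, 1}

    @pytest.mark.parametrize("style", ["structured", "gaussian"])
    def test_caveola_is_a_hollow_shell(self, style):
        blob = generate_blob("CAV", 1, subunit_style=style)
        radial = np.linalg.norm(blob.molecule_positions - blob.center, axis=1)
        # every molecule within the shell thickness of the sphere radius
        assert np.abs(radial - 40.0).max() <= 20.0

    def test_degenerate_zero_radius_subcluster_spread(self):
        # clusters collapse onto their directions but labels stay planted
        blob = generate_blob("S2", 0, subunit_style="gaussian",
                             cluster_sigma=0.0)
        assert len(set(blob.submodule_labels.tolist())) == 5

    def test_errors(self):
        with pytest.raises(ValueError, match="unknown class"):
            generate_blob("S3", 0)
        with pytest.raises(ValueError, match="positive"):
            generate_blob("CAV", 0, radius=-1.0)
        with pytest.raises(ValueError, match="unknown geometry"):
            generate_blob("S1A", 0, radius=40.0)

    def test_seed_reproducibility(self):
        a = generate_blob("CAV", 42)
        b = generate_blob("CAV", 42)
        np.testing.assert_array_equal(a.molecule_positions,
                                      b.molecule_positions)


class TestSimulateBlinks:
    def test_noiseless_identity(self):
        blob = generate_blob("S1A", 3)
        model = BlinkModel(blinks_per_molecule_mean=1.0, lateral_sigma=0.0,
                           axial_sigma=0.0, noise_density=0.0, seed=0)
        scene = simulate_blinks([blob], model)
        got = np.sort(scene.blinks[["x", "y", "z"]].to_numpy(), axis=0)
        want = np.sort(blob.molecule_positions, axis=0)
        np.testing.assert_allclose(got, want)
        assert (scene.truth["molecule_id"] >= 0).all()

    def test_blink_count_expectation(self):
        blobs = [generate_blob("S2", s) for s in range(2)]  # 140 molecules
        model = BlinkModel(blinks_per_molecule_mean=4.0, lateral_sigma=0.0,
                           axial_sigma=0.0, noise_density=0.0, seed=1)
        scene = simulate_blinks(blobs, model)
        n_mol = sum(b.n_molecules for b in blobs)
        expected = 4.0 * n_mol
        # 1 + Poisson(3) per molecule: sd = sqrt(3 * n_mol)
        assert abs(len(scene.blinks) - expected) < 5 * np.sqrt(3 * n_mol)

    def test_anisotropic_localization_error(self):
        # one molecule at the fov center, ten thousand blinks
        center = np.array([[5000.0, 5000.0, 5000.0]])
        blob = GroundTruthBlob("S1A", center, np.zeros(1, dtype=int),
                               center[0])
        model = BlinkModel(blinks_per_molecule_mean=10000.0,
                           lateral_sigma=10.0, axial_sigma=30.0,
                           noise_density=0.0, seed=2)
        scene = simulate_blinks([blob], model, fov=(10000, 10000, 10000))
        stds = scene.blinks[["x", "y", "z"]].to_numpy().std(axis=0)
        np.testing.assert_allclose(stds, [10.0, 10.0, 30.0], rtol=0.05)

    def test_truth_map_is_total(self):
        blob = generate_blob("S1B", 1)
        model = BlinkModel(noise_density=50.0, seed=3)
        scene = simulate_blinks([blob], model)
        assert len(scene.truth) == len(scene.blinks)
        signal = scene.truth["blob_id"] != NOISE
        assert signal.sum() >= blob.n_molecules
        assert (~signal).sum() > 0

    def test_requires_blobs(self):
        with pytest.raises(ValueError):
            simulate_blinks([], BlinkModel())

    def test_model_validation(self):
        with pytest.raises(ValueError):
            BlinkModel(blinks_per_molecule_mean=0.5)
        with pytest.raises(ValueError):
            BlinkModel(lateral_sigma=-1.0)
        with pytest.raises(ValueError):
            BlinkModel(noise_density=-0.1)


class TestGenerateScene:
    def test_empty_scene(self):
        scene = generate_scene({c: 0 for c in CLASS_LABELS}, seed=0,
                               blink_model=BlinkModel(noise_density=0.0))
        assert len(scene.blinks) == 0
        assert len(scene.blobs) == 0

    def test_blob_separation_exceeds_max_pt(self):
        scene = generate_scene({"S1A": 2, "CAV": 3}, seed=1,
                               min_separation=500.0)
        for i, a in enumerate(scene.blobs):
            for b in scene.blobs[i + 1:]:
                gap = cdist(a.molecule_positions, b.molecule_positions).min()
                assert gap > 170.0

    def test_csv_round_trip_is_exact(self, tmp_path):
        scene = generate_scene({"CAV": 2}, seed=2)
        path = tmp_path / "blinks.csv"
        scene.write(path, tmp_path / "truth.json")
        back = read_localizations(path)
        np.testing.assert_array_equal(
            back[["x", "y", "z"]].to_numpy(),
            scene.blinks[["x", "y", "z"]].to_numpy())
        assert (tmp_path / "truth.json").stat().st_size > 0

    def test_deterministic_for_fixed_seed(self):
        a = generate_scene({"S1B": 2, "S2": 1}, seed=7)
        b = generate_scene({"S1B": 2, "S2": 1}, seed=7)
        pd.testing.assert_frame_equal(a.blinks, b.blinks)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_fov_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            generate_scene({"CAV": 100}, fov=(2000.0, 2000.0, 500.0), seed=0)

    def test_blinks_inside_fov(self):
        scene = generate_scene({"S2": 2}, seed=4,
                               blink_model=BlinkModel(noise_density=5.0))
        xyz = scene.blinks[["x", "y", "z"]].to_numpy()
        assert (xyz >= 0).all()
        assert (xyz <= np.asarray(scene.fov)).all()
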