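# cavnet

Network-based analysis of 3D single-molecule localization microscopy (SMLM)
point clouds, built around the caveolin-1 (Cav1) membrane-domain problem:
given millions of stochastic fluorophore "blinks" in (x, y, z), recover the
underlying molecular clusters, classify them, and decompose each cluster
into its structural sub-modules.

Cav1 assembles into four domain classes that are unresolvable by
diffraction-limited microscopy: small S1A scaffolds (the ~8S homo-oligomer,
two stacked polygonal rings of 5–6 molecules), S1B scaffolds (S1A dimers),
larger hemispherical S2 scaffolds, and caveolae (hollow ~145-molecule coats,
50–80 nm across). cavnet is for microscopists and image analysts who want to
ask, quantitatively, how the small scaffolds relate to the large ones.

## Method

The pipeline runs the stages an SMLM field of view needs, in order:

1. **Blink merging.** Each labeled molecule produces many blinks (multiple
   fluorophore activations and antibody labels), forming an artifactual
   dense cluster around the true position. The merge stage repeatedly
   combines the globally closest pair of nodes within a merging proximity
   threshold (MPT, default 19 nm) until no pair remains within the MPT; each
   surviving node is a predicted molecular localization at the centroid of
   its constituent blinks.
2. **Denoising.** A molecule is kept only if its degree in the 80 nm
   proximity graph reaches the 95th percentile of node degrees in
   Monte-Carlo uniform point sets of equal count in the same bounding
   volume; isolated molecules are always dropped.
3. **Segmentation.** Blobs are the connected components of the proximity
   graph at 200 nm, with a minimum size of 5 molecules.
4. **Features.** Every blob gets a 28-dimensional descriptor covering
   counts, extent, shape (PCA ratios, radius of gyration), hollowness, and
   network statistics of its proximity graph at a reference threshold
   (density, characteristic path, clustering, spectral modularity, ...).
5. **Grouping.** Blobs are clustered by k-means on z-scored features
   (default k = 4, the four Cav1 domain classes).
6. **Modules.** For a blob's network `G(V, E_PT)` at proximity threshold PT,
   edges within PT carry a distance similarity `w = exp(-(d/δ)²)` (δ = 25 nm)
   and the network is split by recursive leading-eigenvector bisection of
   the modularity matrix `B = W - k kᵀ / 2m` with Kernighan–Lin fine-tuning,
   maximizing Newman's

   ```
   Q = Σ_c (e_cc − a_c²)
   ```

   the weighted fraction of edge weight within modules minus its
   degree-preserving expectation. Multi-PT curves (components, modules,
   localizations per module versus PT) verify that the decomposition is
   taken in the stable window (60–170 nm).
7. **Module–blob matching.** Modules inherit their parent blob's class and
   are featurized like blobs; the Euclidean distance between class centers
   in pooled z-scored feature space quantifies which blob class each module
   class resembles — the read-out that shows caveolae being built from
   S1B-like units and S2/S1B from S1A-like units.

Because public Cav1 SMLM localization tables are not available, the package
ships a first-class synthetic generator (`cavnet.synthetic`) that plants the
four domain classes with known sub-module labels, simulates blinking
(1 + Poisson multiplicity, ~10 nm lateral / ~30 nm axial error) and uniform
background noise, so every stage is testable against ground truth.

## Worked example

```python
from cavnet import PipelineConfig, generate_scene, run_pipeline

scene = generate_scene({"S1A": 4, "S1B": 4, "S2": 4, "CAV": 4},
                       fov=(8000, 8000, 1000), seed=5)
scene.write("blinks.csv", "truth.json")
bundle = run_pipeline(PipelineConfig(seed=1), input_path="blinks.csv",
                      outdir="out")
print(bundle["manifest"]["counts"])
print(bundle["module_blob_match"].distances.round(2))
```

prints

```
{'n_blinks': 4111, 'n_molecules': 918, 'n_retained': 802, 'n_blobs': 16,
 'n_in_blobs': 802, 'n_featurized': 16, 'n_groups': 4, 'n_modules': 65}
       G1     G2     G3     G4
G1  14.06  14.88  16.31  18.13
G2  10.59  11.63  13.13  15.13
G3   4.15   4.09   5.53   7.80
G4   4.62   3.75   4.31   5.97
```

Reading: 4111 simulated blinks merge into 918 predicted molecules at the
19 nm MPT; denoising keeps 802, which segment into the 16 planted blobs and
cluster into 4 groups ordered by mean localization count (G1 caveolae-like
101 locs ... G4 S1A-like 8.5 locs). In the match matrix (rows = blob groups,
columns = module groups, entries = Euclidean distances between group centers
in pooled z-scored feature space) the column minima show the assembly
hierarchy: caveolae-group modules are closest to S1B-like blobs
(G1 → 4.15 at G3), while S2-group and S1B-group modules are closest to
S1A-like blobs (G2 → 3.75 and G3 → 4.31 at G4).

The same stages are available as a CLI:

```
cavnet simulate --counts CAV=4,S2=4 --out blinks.csv
cavnet merge --mpt 19 --in blinks.csv --out molecules.csv
cavnet pipeline --in blinks.csv --outdir out --seed 1
```

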