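# Methods

This note records the models, algorithms, numerical choices and known
limitations behind cavnet, in the order the pipeline runs them.

## Blink merging

dSTORM-type SMLM reports one localization per fluorophore activation, so a
single labeled molecule appears as a dense cluster of blinks whose spread is
set by the localization error and the antibody label geometry. The merge
stage models molecule recovery purely spatially: while any pair of nodes is
within the merging proximity threshold (MPT), merge the globally closest
pair; the merged node is placed at the unweighted centroid of all original
blinks it contains (equivalently, the blink-count-weighted centroid of the
two merged nodes), which preserves the center of mass of the evidence.

* Convergence is guaranteed: each merge reduces the node count by one, and
  the loop ends exactly when the minimum pairwise distance exceeds the MPT.
* Determinism: distance ties are broken by the lexicographically smallest
  (node id, node id) pair; merged nodes receive fresh, increasing ids.
  Re-running on a converged cloud is the identity.
* The implementation keeps a lazily invalidated heap of candidate pairs and
  a periodically rebuilt k-d tree snapshot; the test suite checks it against
  an independent O(n³) brute-force implementation of the same policy.
* Default MPT 19 nm, with sweeps over 10–20 nm available: molecule counts
  are non-increasing in the MPT, and blob-level classification is expected
  to be insensitive across that window.
* Distances are plain 3D Euclidean; the poorer axial precision is *not*
  rescaled away. Temporal (frame-gap) merging rules and photon-weighted
  averaging are out of scope.

## Denoising

The denoiser asks whether a molecule's local connectivity could have arisen
from structureless background. A molecule is kept iff its degree in the
proximity graph at `pt_denoise` (default 80 nm) reaches the chosen
percentile (default 95) of node degrees pooled over 99 Monte-Carlo uniform
point sets of equal count in the data's bounding box, and its degree is at
least 1 (isolated molecules — monomers at the analysis scale — are always
removed). The comparison is `degree >= threshold` rather than strictly
greater: for very tight clusters the null distribution saturates at the
complete-graph degree, and a strict test would absurdly reject a maximally
connected cluster. The replicate count is fixed and seeded, so the decision
is reproducible.

Limitation: the null is uniform in the axis-aligned bounding box. Real
backgrounds with large-scale density gradients (e.g. cell edges) would need
a stratified null; at desk scale with planted scenes the uniform null is
exact by construction.

## Segmentation

Blobs are connected components of the retained cloud's proximity graph at
`pt_segment` (default 200 nm), keeping components with at least
`min_blob_size` molecules (default 5, so the smallest S1A scaffolds
survive). Components are ordered by their smallest molecule index, making
blob ids invariant to rigid motion and stable under input permutation.

## The 28-feature descriptor

One fixed, versioned registry of 28 features describes any point set (blob
or module): counts and blink statistics (3), axis-aligned extent and
bounding-box volume (4), radius of gyration and pairwise-distance summaries
(4), hollowness (1), PCA shape ratios and covariance-ellipsoid volume (4),
and statistics of the proximity graph at a reference threshold, default
80 nm (12: density, degree mean/variance, transitivity, characteristic
path, diameter, component count, spectral modularity, module count, mean
module size, degree assortativity, mean edge length).

Definitions worth stating:

* **Hollowness** = (distance from the centroid to its nearest point) /
  (mean radial distance of all points from the centroid); ≈ 1 for a hollow
  shell, ≪ 1 for a filled set, defined 0 below 4 points. For an n-point
  shell the centroid's sampling offset (~R/√n) keeps the value slightly
  below 1.
* **Characteristic path** = mean shortest-path hop count over connected
  node pairs only; 0 for an edgeless graph.
* **Shape ratios**: with covariance eigenvalues λ1 ≥ λ2 ≥ λ3, linearity
  (λ1−λ2)/λ1, planarity (λ2−λ3)/λ1, sphericity λ3/λ1 (they sum to 1).
  The ellipsoid volume uses semi-axes √(5λᵢ), the uniform solid ellipsoid
  with matching covariance — a convex-hull proxy that needs no mesh.
* Degenerate rules: a single point has all graph statistics 0 (with one
  component and one module of size one); degree assortativity is 0 whenever
  it is undefined (regular graphs).

All features are translation-invariant; the axis-aligned ranges and
bounding-box volume (slots 4–7) are the only rotation-variant entries,
mirroring how acquisition software reports cluster "size" as an X-range.

## Proximity networks and edge weighting

A blob's network at proximity threshold PT has an edge for every molecule
pair within PT. Three edge-weight kernels are provided; the default is a
Gaussian distance similarity with a *fixed* physical decay scale,

    w(d) = exp(−(d/δ)²),  δ = 25 nm,

independent of the PT. The scale was calibrated on the synthetic blobs so
that intra-oligomer neighbour spacings (~10–15 nm) carry near-full weight
while inter-module gaps (≥ 40 nm) are strongly suppressed; any δ in
roughly 20–30 nm behaves equivalently. Two properties motivated this choice
over the PT-normalized linear kernel `w = 1 − d/PT` (still available as
`weighting="linear"`, plus `"binary"`):

1. **Sub-structure on complete graphs.** Blobs smaller than the PT form
   topologically complete networks; only the weights can carry spatial
   structure. With the linear kernel at PT = 80 nm the weight contrast
   between 10 nm and 50 nm pairs is only 0.88 vs 0.38, and on a
   caveola-like blob the maximum-modularity partition merges the planted
   sub-clusters (Q saturates near 0.23 with 4 modules, confirmed by
   independent optimizers); with the Gaussian kernel the contrast is 0.85
   vs 0.02 and the seven planted sub-clusters are recovered exactly with
   Q ≈ 0.7.
2. **Threshold stability for free.** Because δ does not change with the PT,
   edges added at large PTs carry negligible weight, so the module
   decomposition is constant over the whole 60–170 nm window — the regime
   in which these blobs form a single connected component but have not yet
   blurred together.

## Spectral modularity decomposition

Modules maximize Newman modularity, in its weighted form

    Q = (1/2m) Σ_ij (W_ij − k_i k_j / 2m) δ(c_i, c_j),

via recursive bisection with the leading eigenvector of the modularity
matrix `B = W − k kᵀ/2m`, using the generalized modularity matrix
`B^(g)_ij = B_ij − δ_ij Σ_{k∈g} B_ik` on subgraphs. After each proposed
bisection a Kernighan–Lin sweep moves single nodes greedily (each node once
per pass, keeping the best intermediate state) until no pass improves the
split. Recursion stops when the leading eigenvalue is ≤ 1e−10, when a split
leaves one side empty, or when the modularity gain is ≤ 1e−12. Eigenvectors
are oriented so their first nonzero entry is positive, making the partition
deterministic. Connected components are split first (`decompose_blob`);
`spectral_modules` itself requires a connected graph, since modularity is
meaningless across components. A zero-total-weight graph has Q defined as 0.

On every fixture graph small enough for exhaustive partition enumeration
(≤ 8 nodes) the spectral partition attains at least 95% of the true maximum
Q, and the analytic cases (complete graph: indivisible, Q = 0; two
triangles joined by a bridge: Q = 5/14) are met exactly. Dense eigensolvers
are used throughout — blobs at desk scale have ≤ ~150 molecules, where a
full `eigh` is faster than iterative methods.

## Group learning and matching

Blobs are clustered with k-means (20 restarts, seeded) on z-scored
features; constant features z-score to 0. The pipeline default is k = 4 —
the four known Cav1 domain classes; `k="auto"` selects k in 2..8 by
silhouette. Groups are relabeled in order of descending mean localization
count (caveolae-like first) and named G1..Gk. On desk-scale synthetic
populations the 4-group clustering recovers the planted classes with
adjusted Rand index 1.0; silhouette-based AUTO selection tends to prefer
k = 3 because S1A and S1B (a monomer and its dimer) are adjacent in feature
space — one reason the class count is an explicit pipeline parameter rather
than always inferred.

Two collections are matched by the Euclidean distances between their group
centers computed in a feature space z-scored with statistics pooled over
both collections; the per-column argmin is the closest group. Pooled
normalization makes the matching invariant to any feature-wide affine
rescaling applied to both collections, and reduces to the trivial identity
(zero diagonal) when a collection is matched against itself.

## Module–blob matching

Each module found at the module PT (default 80 nm, inside the stable
window) is featurized with the same 28-feature registry and inherits its
parent blob's class. Modules are pooled per parent class and represented by
the mean feature vector in the pooled z-scored space (per-module distances
are also emitted for diagnostics). The match matrix has blob classes as
rows and module classes as columns; the column argmin names the blob class
most similar to that class's modules.

## The synthetic generator

The generator is the package's study system: four planted blob classes with
known sub-module labels.

* **S1A** — two stacked polygonal rings of 5–6 molecules (ring radius 6 nm,
  ring separation 12 nm, positional jitter 1 nm), randomly oriented;
  10–12 molecules, < 20 nm across. Each ring is a planted sub-module.
* **S1B** — two independently generated S1A units with centers 16 nm apart,
  about one unit diameter: a contact dimer. Four planted sub-modules.
* **S2** — five sub-units at evenly spaced directions (pole plus ring at
  polar angle 75°, small angular jitter) on a 40 nm-radius hemisphere;
  70 molecules.
* **CAV** — seven sub-units at approximately even directions (Fibonacci
  sphere, random rotation, angular jitter) on a 40 nm-radius shell;
  145 molecules, hollow by construction.

S2 and CAV sub-units default to *structured* building blocks — S1A-like
double rings of 14 molecules for S2, S1B-like dimers of ~21 for CAV —
making the assembly hierarchy (rings → S1A → S1B → caveolae; S1A → S2)
literal in the geometry. `subunit_style="gaussian"` plants isotropic
Gaussian clusters (spread 5 nm; CAV radial positions uniform within a
20 nm shell thickness) of the same sizes instead, a useful null shape for
module-recovery benchmarks. Module counts and modularity are insensitive to
the style (CAV: 7 modules, Q ≈ 0.70 either way; S2: 5 modules), but only
the structured defaults make module *features* resemble their building
blocks, which is what the module–blob matching read-out measures.

Blinking: each molecule emits `1 + Poisson(mean − 1)` blinks (≥ 1 by
construction; default mean 4), displaced by an anisotropic Gaussian error
(defaults 10 nm lateral, 30 nm axial). Background noise is homogeneous
Poisson at a density per µm³ (default 2). Scenes place blob centers on a
shuffled grid whose spacing guarantees a minimum inter-blob molecule
separation (default 500 nm, comfortably above the largest analysis PT), in
a default 5×5×1 µm field of view — large fields are unnecessary at desk
scale. All randomness flows from one seed through spawned substreams, so
scenes are bit-reproducible; blinks are clipped to the field of view.

What the generator does **not** emulate: camera frames and PSF rendering,
drift, photophysics kinetics beyond blink multiplicity, label
stoichiometry variation, and density gradients in the background. Passing
tests therefore demonstrate the pipeline's correctness and its behavior
under the stated noise model, not performance on any particular
instrument's data.

## Problem sizes and reproducibility

The test suite and the acceptance script run planted populations of ~12
blobs per class (~2,500 molecules per scene before blinking), single blobs
of 11–145 molecules, and merge inputs up to a few thousand blinks — sizes
chosen so the complete analysis of a scene takes seconds while every
recovery statement is still measured, not assumed. Every pipeline output
embeds the package version, seed and configuration in a run manifest;
fixed seeds reproduce all outputs byte-for-byte.

## Known limitations

* The linear `1 − d/PT` kernel is retained for comparison but cannot
  resolve sub-structure of blobs much smaller than the PT (see above).
* Hollowness uses the centroid-to-nearest-point ratio, not a mesh or
  alpha-shape volume; it saturates for very small n.
* Silhouette-based k selection merges adjacent classes at desk scale;
  class counts should be treated as a modeling choice where the domain
  provides one.
* Blink merging is purely spatial; frame-aware merging (duty-cycle models)
  would disambiguate molecules closer than the localization error.
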