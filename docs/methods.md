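# Methods

## Pipeline and assumptions

An 8-bit grayscale image (RGB inputs are first collapsed to Rec. 601
luminance, rounded to the nearest integer — scalar node values are
required by the edge-weight formula) is scaled to [0, 1] by fixed-range
division by 255. Per-image min/max scaling was deliberately rejected:
it would make identical patches from different images map to different
graphs and contradicts the fixed 0–255 input range.

The image is tiled into non-overlapping p × p patches; p must divide
both dimensions (the error message lists the valid divisors). Patch
traversal and pixel-to-node numbering are both row-major. No convention
is forced by the math — any consistent order yields a permutation of
the same feature multiset (the features are permutation-equivariant) —
so the common raster order is used everywhere.

## Graph construction

Edge weights are |v_j − v_i|, so they live in [0, 1] and are invariant
to adding a constant to every pixel. Three graph types:

* **grid2d** — 4-connected (von Neumann) lattice; 8-connectivity would
  also be defensible but 4-connectivity is the standard "grid lattice"
  and keeps the Laplacian maximally sparse. |E| = 2p(p−1).
* **pairwise** — complete graph, |E| = Z(Z−1)/2 with Z = p².
* **knn** — neighborhoods are computed in *intensity* space (|Δvalue|),
  the only node attribute the model defines; spatial or mixed metrics
  are possible variants, not implemented. Each node proposes its k
  nearest, ties broken by ascending node index (deterministic), and the
  edge set is the union of proposals. k = Z−1 recovers the pairwise
  graph; a typical choice ties k to the patch side length.

Self-loops are never created; the diagonal is handled entirely by the
degree matrix.

## The modified weighted Laplacian

L = D − A with A the weighted adjacency and D the diagonal of
*unweighted* degrees (row sums of the binary adjacency S). This mixing
is the point: row i of A has exactly D_ii nonzero entries, each ≤ 1, so
L_ii = D_ii ≥ Σ_j≠i |L_ij| always, with strict inequality whenever any
incident weight is below 1. Equality occurs only when every incident
edge connects pure black to pure white — so dominance is asserted
weakly everywhere and strictly under the some-weight-below-1 condition,
rather than claiming strictness unconditionally. Weak diagonal
dominance of a symmetric matrix with nonnegative diagonal implies
positive semi-definiteness; tests verify min eigenvalue ≥ −1e−9 with a
dense eigensolver.

Zero-weight edges (equal-valued pixels) are structural: they contribute
to D but vanish in A. Dropping them would change the centers and is a
different (wrong) operator; a regression test covers this.

Matrices are dense numpy arrays; for p ≤ 8 (Z ≤ 64) sparsity buys
nothing. Adjacency matrices are produced by `networkx.to_numpy_array`
over graphs held as `networkx.Graph` objects.

## Gershgorin features

r_i = Σ_j≠i |L_ij|, c_i = L_ii. Since L is symmetric, its Gershgorin
discs are real intervals; since c_i ≥ r_i, the union ∪[c_i − r_i,
c_i + r_i] sits in the nonnegative half-line, consistent with PSD. The
P × N × 2 tensor always contains 2·M·N numbers regardless of p — the
reduction trades the N × N matrix for exactly two numbers per node.
The extraction is irreversible: distinct Laplacians can share (R, C).

Two serializations are provided: `layout_2d` gives a (2, P·N, 1) plane
(row 0 radii, row 1 centers, patch-concatenated); `layout_1d` gives a
flat vector, by default interleaved [R₁, C₁, R₂, C₂, …] so each patch's
two vectors stay adjacent ("blocked" [all R, all C] is available via an
argument — the flat order is a genuinely open convention, so it is
configurable and documented rather than hard-coded).

## CNN architecture specs and parameter counting

The classifier skeleton is fixed: three blocks of [conv, 32 filters,
same padding, bias, ReLU; average pool], then flatten, dense 512, dense
512, dropout 0.1, softmax output. The GCFE variant uses 1×3 kernels and
1×2 pools on the (2, P·N, 1) plane; the standard-Laplacian variant uses
3×3 kernels and 2×2 pools on per-patch Laplacians stacked vertically
into (P·N, N, 1) — the only stacking found consistent with the target
parameter counts at patch sizes 14 and 28. Pools use the Keras default
of stride equal to the pool size per dimension with valid padding
(floor on odd dims); for the 1×2 pool this preserves the 2-row height
while halving the width, which is what keeps the GCFE model size
independent of patch size.

Parameters are counted in closed form (conv: kh·kw·c_in·f + f; dense:
n_in·u + u; pool/flatten/dropout: 0), giving exactly 3,504,879 for the
GCFE model on a 28 × 28 image with 47 classes and 38,841,263 for the
Laplacian model at patch size 14. Counts for Laplacian patch sizes 2, 4
and 7 under this skeleton do not match any published reference values
we are aware of (p = 2 even pools to zero width), so they are not
asserted anywhere.

`train_and_evaluate` is an optional harness requiring torch at runtime
(sparse-categorical cross-entropy via `CrossEntropyLoss`, Adam, 10
epochs, 70/15/15 split). The core package, all feature extraction and
all parameter accounting run without any deep-learning framework; the
missing-backend path raises a dedicated `MissingBackendError`.

## Reporting utilities

* `sample_sd` uses the n−1 denominator — the convention that reproduces
  the published dispersion values this package's tests pin (population
  SD does not).
* `pct_diff` is the symmetric mean-denominator percentage difference
  |a−b| / ((a+b)/2) · 100, again the convention matching the pinned
  values; baseline-relative difference does not.
* `z_score` is the plain (x − mean)/SD against a reference series. No
  aggregate "average Z-score" is provided: no defensible aggregation
  over the published accuracy tables reproduces the headline averages,
  so only the standard definition is shipped.

One published table cell (pairwise spectral embedding, balanced-set
patch 4, 95.86) is inconsistent with its neighbors — almost certainly a
typo — and is excluded from every computation here.

## Synthetic data

The fixtures module generates constant, checkerboard, gradient and
seeded-random uint8 images, plus a fixed 4 × 4 seeded sample
(`fig2_sample`) used for the documentation walkthrough; the walkthrough
asserts only structurally forced facts (pairwise centers all 3, radii
≤ 3). These fixtures exercise every code path — degenerate zero-weight
graphs, maximal-contrast edges, generic values — but they are not
natural images: they say nothing about classification accuracy on real
datasets, only about the algebraic correctness of the extraction.

## Problem sizes and numerics

Random-patch sweeps use sizes 2–8 (Z ≤ 64), where dense eigensolvers
are exact and instantaneous; the acceptance sweep covers 216 patches
across all three graph types. Tolerances: symmetry/trace checks at
numpy `allclose` defaults; PSD and disc-inclusion at 1e−9 (eigensolver
round-off); dominance at 1e−12. All randomness flows through
`numpy.random.default_rng` with explicit seeds; feature extraction
itself is fully deterministic.

## Known limitations

* The reduction is lossy and non-parametric: always exactly 2 numbers
  per node, with no dial to ask for more or fewer features.
* K-NN graph semantics (intensity metric, union symmetrization, index
  tie-break) are this package's documented choices among several
  defensible ones; results depend on them.
* Grayscale conversion of RGB inputs is likewise a package choice
  (Rec. 601); any scalarization would work with the rest unchanged.
* Tighter eigenvalue-inclusion regions (e.g. Brauer ovals) would give
  sharper features and are out of scope.
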