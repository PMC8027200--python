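# Methods

This note records the model implemented by `vecmap`, its tunable
parameters, the numerical choices made where the design was open, what
the synthetic-data generators do and do not emulate, and the package's
known limitations.

## Representation: one mean-shift step per occupied voxel

A density map is reduced to a field of unit vectors. After resampling to
the working spacing and zeroing sub-contour voxels, each occupied voxel
**x**ᵢ is assigned the kernel- and density-weighted mean position of its
occupied neighborhood,

y_i = Σ_n k(x_i − x_n) Φ(x_n) x_n / Σ_n k(x_i − x_n) Φ(x_n),
k(p) = exp(−1.5 |p/σ|²),

and carries the unit vector (y_i − x_i)/|y_i − x_i|. This is a *single*
mean-shift step, not an iteration to convergence: the one-step weighted
mean already defines the local uphill direction, and iterating would only
change which voxels collapse onto exactly coincident modes (slightly
altering the dropped-vector count) without changing the directions that
drive the alignment. Voxels with |y_i − x_i| ≤ 1e-6 × spacing — density
maxima and perfectly symmetric neighborhoods — carry no meaningful
direction and are dropped; their count is reported on the field.

The kernel is truncated at 2σ, where its weight has fallen to
exp(−6) ≈ 0.0025; sums over the truncation ball are computed as dense
convolutions of the contoured density with precomputed kernel lattices.
The per-voxel `mean_shift_target` evaluates the same sum directly and
serves as the independent check on the convolution path.

### Parameters

| parameter | default | units | role |
|---|---|---|---|
| voxel spacing | 7 | Å | working lattice for scoring; maps are trilinearly resampled to it |
| bandwidth σ | 8 | Å | mean-shift kernel width; also the pre-CC smoothing kernel |
| contour Φ_thr | map-specific | map units | defines the occupied volume; never rescaled by resampling |
| coarse angle | 30 | degrees | z–y–z Euler sampling interval of the rotational scan |
| refinement step | 5 | degrees | local per-axis angular scan around the ten best coarse poses |
| top-k | 10 | poses | number of ranked superimpositions returned |

Resampling uses trilinear interpolation (exact on linear fields, cheap,
standard) onto the occupied bounding box padded by one kernel truncation
radius (16 Å) per side, so mean-shift sums near the original boundary are
not edge-clipped. Contouring happens after resampling, with the original
contour value applied to the interpolated densities.

## DOT score and the FFT translational scan

The alignment objective is the sum over co-located voxel pairs of the dot
products of their unit vectors; every occupied voxel has equal weight.
Because the score is a sum of three component-wise products, the full
translation lattice for a fixed rotation is the sum of three scalar
cross-correlations, evaluated with zero-padded real FFTs (padded to
ref + query − 1 per axis, so circular wraparound cannot fabricate
overlaps). The scan is exact: on lattice-resident fields it reproduces a
brute-force pairwise accumulation to ~1e-15.

**Rasterization of rotated fields.** Rotations move vector positions off
the lattice. Two rasterizations are implemented:

* *nearest-node snapping* with colliding vectors averaged and
  renormalized (`rotate_field`, `dot_score_direct`) — this is the
  definition used for reported DOT scores and overlap counts, and the
  brute-force oracle for the FFT path;
* *trilinear splatting* (each rotated vector spreads its direction over
  the eight surrounding nodes with trilinear weights), used inside the
  rotational search to score candidate rotations.

The search uses splatting because the snapped score landscape is noisy
at a 7 Å lattice: collision-averaging-then-renormalizing can inflate the
score of poses several degrees off the optimum, which on toy maps
produced recovered rotations 7–10° from the planted truth. Splatting is
a smooth function of the rotation, reduces to exact scattering for
on-lattice fields (so self-alignment still yields DOT = N exactly and
the FFT/brute-force equivalence is untouched), and restores recovery to
within the 5° refinement step. Final results are re-scored with the
snapped `dot_score_direct`, so reported DOT values keep the discrete
matched-pair semantics.

**Rotation sampling.** Euler z–y–z triplets on a regular grid at the
coarse interval, deduplicated greedily (in lexicographic order, so the
identity always survives and ordering is reproducible) so that no two
retained rotations are within half the interval in geodesic distance. At
90° this yields exactly the 24 proper rotations of the cube; at 30° it
yields 744 rotations. Refinement scans ±interval in 5° steps about each
Cartesian axis independently, in two greedy passes over the axes, for
each of the ten best coarse poses; a joint 3D sub-grid scan (≈13³ FFT
scans per pose) would be two orders of magnitude more expensive for
marginal gain. The rotation pivot is the centroid of the query's
occupied volume; translations are reported in Å in the reference frame.

**Determinism.** Ties in the translation scan break at the
lexicographically smallest lattice offset; ties in rank break by coarse
rotation index and then lexicographic translation. Identical inputs give
byte-identical output tables.

## CC and Laplacian-CC baselines

CC is the Pearson-style correlation of density values with each map's
mean taken over its own above-contour voxels and the numerator restricted
to the superimposed overlap. Because the means and denominator sums
depend only on each map's own occupied voxels, the whole translation
lattice of CC for a fixed rotation is a single FFT correlation of the
mean-adjusted, contour-masked densities divided by a constant — no
per-pose renormalization is needed. Top poses are re-scored directly
from the definition. The Laplacian variant applies a 6-neighbor discrete
Laplacian (divided by spacing², nearest-edge boundary so constants map
to zero) to both maps before correlation, while occupancy still follows
the original contour; it emphasizes 3D edges.

## Significance: clustered Z-score

The DOT score grows with map size, so database rankings use
Z = (best − mean)/SD, where mean and SD come from the per-rotation best
scores of the coarse scan and "best" is the refined best score. Before
standardizing, the per-rotation scores are clustered by single linkage
with a cutoff of 0.2 × (max − min); only the largest cluster defines the
null. On the line, single linkage reduces to splitting the sorted scores
at gaps exceeding the cutoff (O(n log n)); the test suite cross-checks
this against scipy's hierarchical single linkage. When cluster sizes
tie, the cluster with the smaller minimum is taken — the conservative
choice, since a lower-scoring null inflates no Z-scores. The SD is the
population standard deviation; with ≥ 24 rotations the distinction from
the sample SD is immaterial, and affine invariance holds either way.
Degenerate distributions (fewer than three rotations, zero variance in
the largest cluster) raise rather than returning an arbitrary value.

Retrieval quality is summarized by tier fractions: with m same-class
targets present, the first (second) tier is the fraction of them within
the top m (2m) ranks. A query whose class has no other member yields
(0, 0, 0) rather than an error. Pose deviations from a reference
superimposition can be summarized either as model RMSD (no
re-superposition; the minimum over a supplied list of
symmetry-equivalent references) or as the arc-length score
ALCPS = 2πrθ/360 with r in Å and θ in degrees (θ up to 360 accepted).

## Synthetic data: what it emulates, what it does not

`simulate_map` places an isotropic Gaussian of sd = 0.225 × resolution
and unit peak amplitude at each atom (the molmap convention; Gaussians
truncated at 5 sd, where the weight is ~3e-6), contoured at 0.2.
`make_toy_model` generates a persistent random walk of pseudo-Cα atoms
at 3.8 Å steps — compact, chain-like, asymmetric. `make_toy_volume`
produces procedural solids (an L-shape with three mutually unequal arms
and an off-axis knob, verified to have no rotational self-symmetry; a
helical tube; an unequal dumbbell). `plant_transform` rigidly moves a
grid by a z–y–z rotation plus translation with trilinear resampling and
returns the exact ground-truth transform; its pivot is snapped to the
nearest lattice node so that pure lattice rotations combined with
whole-voxel shifts are exact voxel permutations, which gives the test
suite lossless planted cases alongside the lossy general ones.

These generators emulate the *geometry* of EM maps — smooth blobs at a
nominal resolution, contoured occupancy, known rigid displacements. They
do not emulate experimental noise spectra, B-factor falloff, solvent
background, masking artifacts, preferred-orientation anisotropy, or
conformational heterogeneity between maps of the same molecule. Passing
recovery tests therefore demonstrates the correctness of the search
machinery (scores, FFT scan, refinement, bookkeeping of transforms), not
retrieval performance on experimental EMDB data.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
toy volumes of 16–20 voxels per side at 7 Å (≈170–290 vectors),
simulated proteins of 70–150 pseudo-residues (≈40–90 vectors at 7 Å),
100 random sparse field pairs in boxes up to 16³ for the FFT/brute-force
equivalence, and a six-map two-class retrieval. These sizes keep a full
run in the minutes range on one CPU while exercising every code path;
the method itself scales to real map sizes (the FFT scan is
O(M log M) per rotation in the padded voxel count M).

## Known limitations

* Translations are recovered on the voxel lattice; sub-voxel shifts
  contribute up to half a voxel per axis of irreducible error.
* Rotated-field DOT scores depend on the rasterization; nearest-node
  round trips lose vectors to collisions at large angles (≈20 % at a 20°
  rotation of a 7 Å toy lattice), which is inherent to snapping a
  rotated lattice.
* Maps with non-orthogonal cells are rejected rather than interpreted.
* The contour level is taken as given (an explicit CLI input when absent
  from metadata); no automatic thresholding is attempted.
* Symmetry of the molecule is not detected; symmetry-equivalent reference
  poses for RMSD evaluation must be supplied by the caller.
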