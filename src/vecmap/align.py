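"""Exhaustive rigid-body alignment of vector fields and density grids.

The search samples rotations on a z-y-z Euler grid (default 30 degrees,
deduplicated by geodesic distance), and for each rotation performs a full
translational scan with FFTs.  For the DOT score the three vector
components are rasterized into three scalar grids and the score lattice is
the sum of the three cross-correlations; for CC a single correlation of
mean-adjusted, contour-masked densities is used.  The ten best coarse
poses are refined by an angular scan at 5-degree steps about each axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sp_fft
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .map_io import DensityGrid
from .preprocess import laplacian_filter
from .vectorize import VectorField, compute_vector_field

__all__ = ["RigidTransform", "AlignmentResult", "enumerate_rotations",
           "rotate_field", "dot_score_direct", "fft_translation_scan",
           "cc_score", "search"]


@dataclass
class RigidTransform:
    """Rotation about a pivot followed by a translation (all in Angstrom).

    Maps a query-frame point p to ``R (p - pivot) + pivot + translation``
    in the reference frame.
    """

    rotation: np.ndarray
    translation: np.ndarray
    pivot: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        self.pivot = np.asarray(self.pivot, dtype=np.float64).reshape(3)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not math.isclose(float(np.linalg.det(R)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation must be proper (det = +1)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.asarray(points, dtype=np.float64)
        return (p - self.pivot) @ self.rotation.T + self.pivot + self.translation

    def to_origin_form(self) -> "RigidTransform":
        """Equivalent transform with the pivot moved to the origin."""
        b = self.pivot - self.rotation @ self.pivot + self.translation
        return RigidTransform(self.rotation, b)

    def inverse(self) -> "RigidTransform":
        # forward is p -> R p + b with b = pivot - R pivot + translation
        b = self.pivot - self.rotation @ self.pivot + self.translation
        return RigidTransform(self.rotation.T, -self.rotation.T @ b)

    def geodesic_angle_to(self, other: "RigidTransform | np.ndarray") -> float:
        """Rotation difference in degrees (angle of R_other^T R_self)."""
        R_other = other.rotation if isinstance(other, RigidTransform) else \
            np.asarray(other)
        cos = (np.trace(R_other.T @ self.rotation) - 1.0) / 2.0
        return math.degrees(math.acos(min(1.0, max(-1.0, cos))))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(),
                "translation": self.translation.tolist(),
                "pivot": self.pivot.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]),
                   np.asarray(d.get("pivot", np.zeros(3))))


@dataclass
class AlignmentResult:
    """A candidate superimposition with its scores and rank."""

    transform: RigidTransform
    dot_score: float
    cc: float
    overlap: int
    rank: int

    def __post_init__(self) -> None:
        if self.dot_score > self.overlap + 1e-6:
            raise ValueError("DOT score cannot exceed the matched-pair count")
        if np.isfinite(self.cc) and abs(self.cc) > 1 + 1e-9:
            raise ValueError("CC must lie in [-1, 1]")


def enumerate_rotations(interval: float) -> list[np.ndarray]:
    """Proper rotations sampled on a z-y-z Euler grid at ``interval`` degrees.

    The grid covers the full Euler ranges and is deduplicated so that no
    two returned rotations are within ``interval / 2`` geodesic distance.
    Order is deterministic (lexicographic in the Euler triplet); the
    identity rotation always comes first.
    """
    if not (0 < interval <= 180) or 360.0 % interval != 0:
        raise ValueError("interval must divide 360 and lie in (0, 180]")
    alphas = np.arange(0.0, 360.0, interval)
    betas = np.arange(0.0, 180.0 + interval / 2, interval)
    betas = betas[betas <= 180.0 + 1e-9]
    gammas = np.arange(0.0, 360.0, interval)
    triplets = [(a, b, c) for a in alphas for b in betas for c in gammas]
    rots = Rotation.from_euler("ZYZ", triplets, degrees=True)
    quats = rots.as_quat()

    # geodesic angle between rotations = 2 arccos(|q1 . q2|)
    threshold = math.cos(math.radians(interval / 2) / 2.0)
    kept: list[int] = []
    kept_q = np.empty((0, 4))
    for i, q in enumerate(quats):
        if len(kept) and np.max(np.abs(kept_q @ q)) > threshold + 1e-12:
            continue
        kept.append(i)
        kept_q = np.vstack([kept_q, q])
    mats = rots.as_matrix()
    return [mats[i] for i in kept]


def _rasterize(field: VectorField) -> tuple[np.ndarray, np.ndarray]:
    """Scatter directions onto a dense (3, nx, ny, nz) grid.

    Returns the component grids and the minimum voxel index (the grid's
    lattice offset relative to the field origin).
    """
    base = field.indices.min(axis=0)
    shape = tuple(field.indices.max(axis=0) - base + 1)
    comps = np.zeros((3,) + shape)
    rel = field.indices - base
    comps[:, rel[:, 0], rel[:, 1], rel[:, 2]] = field.directions.T
    return comps, base


def _merge_collisions(indices: np.ndarray, directions: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Average directions landing on the same node, then renormalize.

    Nodes whose averaged direction cancels to (numerically) zero are
    dropped so the unit-norm invariant survives.
    """
    uniq, inv = np.unique(indices, axis=0, return_inverse=True)
    summed = np.zeros((len(uniq), 3))
    np.add.at(summed, inv, directions)
    counts = np.bincount(inv, minlength=len(uniq)).astype(float)
    mean = summed / counts[:, None]
    norms = np.linalg.norm(mean, axis=1)
    keep = norms > 1e-9
    return uniq[keep], mean[keep] / norms[keep, None]


def rotate_field(field: VectorField, rotation: np.ndarray) -> VectorField:
    """Rotate a vector field about its centroid and snap back to the lattice.

    Directions are rotated exactly; positions are rotated and re-binned to
    the nearest lattice node, with colliding vectors averaged and
    renormalized.
    """
    if len(field) == 0:
        raise ValueError("cannot rotate an empty field")
    R = np.asarray(rotation, dtype=np.float64)
    c = field.centroid()
    pos = (field.coords - c) @ R.T + c
    dirs = field.directions @ R.T
    idx = np.rint((pos - field.origin) / field.spacing).astype(np.int64)
    idx, dirs = _merge_collisions(idx, dirs)
    return VectorField(indices=idx, directions=dirs, spacing=field.spacing.copy(),
                       origin=field.origin.copy(), n_dropped=field.n_dropped)


def dot_score_direct(ref: VectorField, query: VectorField,
                     transform: RigidTransform) -> tuple[float, int]:
    """Brute-force DOT score of a transform: sum of dots over matched nodes.

    The query positions are transformed, snapped to the reference lattice
    (collisions averaged and renormalized), and matched to reference
    vectors occupying the same node.
    """
    if not np.allclose(ref.spacing, query.spacing):
        raise ValueError("fields must share voxel spacing")
    pos = transform.apply(query.coords)
    dirs = query.directions @ transform.rotation.T
    idx = np.rint((pos - ref.origin) / ref.spacing).astype(np.int64)
    idx, dirs = _merge_collisions(idx, dirs)
    lookup = {tuple(i): d for i, d in zip(ref.indices, ref.directions)}
    score = 0.0
    overlap = 0
    for i, d in zip(idx, dirs):
        rd = lookup.get(tuple(i))
        if rd is not None:
            score += float(rd @ d)
            overlap += 1
    return score, overlap


@dataclass
class TranslationScan:
    """Score lattice over all translations of an embedded field/grid pair."""

    scores: np.ndarray          # full correlation lattice, C-order
    offset0: np.ndarray         # voxel shift corresponding to scores[0,0,0]
    base_shift: np.ndarray      # Cartesian shift (A) at zero voxel offset
    spacing: np.ndarray

    def translation(self, lattice_index) -> np.ndarray:
        """Cartesian translation (Angstrom) for a score-lattice index."""
        s = np.asarray(lattice_index) + self.offset0
        return self.base_shift + s * self.spacing

    def best(self) -> tuple[float, np.ndarray]:
        """Highest score and its translation; ties break at the
        lexicographically smallest lattice index (C-order argmax)."""
        flat = int(np.argmax(self.scores))
        idx = np.unravel_index(flat, self.scores.shape)
        return float(self.scores[idx]), self.translation(idx)


def _correlate_full(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Sum over channels of full cross-correlations: out[k] = sum_c sum_j
    A_c[j + k - (nB-1)] B_c[j], computed with zero-padded FFTs."""
    na = np.array(A.shape[1:])
    nb = np.array(B.shape[1:])
    shape = tuple(na + nb - 1)
    acc = None
    for c in range(A.shape[0]):
        fa = sp_fft.rfftn(A[c], shape)
        fb = sp_fft.rfftn(B[c][::-1, ::-1, ::-1], shape)
        acc = fa * fb if acc is None else acc + fa * fb
    return sp_fft.irfftn(acc, shape)


def _scan(A: np.ndarray, a_base: np.ndarray, B: np.ndarray, b_base: np.ndarray,
          origin_diff: np.ndarray, spacing: np.ndarray) -> TranslationScan:
    nb = np.array(B.shape[1:])
    scores = _correlate_full(A, B)
    offset0 = np.asarray(a_base) - np.asarray(b_base) - (nb - 1)
    return TranslationScan(scores=scores, offset0=offset0,
                           base_shift=np.asarray(origin_diff, dtype=float),
                           spacing=np.asarray(spacing, dtype=float).copy())


def fft_translation_scan(ref: VectorField, query: VectorField) -> TranslationScan:
    """DOT score at every lattice translation via three FFT correlations.

    The fields are embedded in zero-padded lattices large enough that
    circular wraparound cannot create spurious overlaps; the result equals
    the brute-force pairwise sum at every translation.
    """
    if len(ref) == 0 or len(query) == 0:
        raise ValueError("cannot scan empty fields")
    if not np.allclose(ref.spacing, query.spacing):
        raise ValueError("fields must share voxel spacing")
    A, a_base = _rasterize(ref)
    B, b_base = _rasterize(query)
    return _scan(A, a_base, B, b_base, ref.origin - query.origin, ref.spacing)


def _splat(coords: np.ndarray, dirs: np.ndarray, origin: np.ndarray,
           spacing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize off-lattice vectors by trilinear splatting.

    Each vector distributes its direction over the eight surrounding
    lattice nodes with trilinear weights.  For vectors already on lattice
    nodes this reduces to exact scattering, so lattice-resident fields
    score identically to :func:`_rasterize`; for rotated (off-lattice)
    positions it gives a much smoother score landscape than nearest-node
    snapping.
    """
    rel = (coords - origin) / spacing
    base = np.floor(rel.min(axis=0)).astype(np.int64)
    shape = tuple(np.floor(rel.max(axis=0)).astype(np.int64) - base + 2)
    comps = np.zeros((3,) + shape)
    f0 = np.floor(rel).astype(np.int64)
    frac = rel - f0
    for corner in range(8):
        off = np.array([(corner >> a) & 1 for a in range(3)])
        w = np.prod(np.where(off, frac, 1.0 - frac), axis=1)
        idx = f0 + off - base
        for c in range(3):
            np.add.at(comps[c], (idx[:, 0], idx[:, 1], idx[:, 2]),
                      w * dirs[:, c])
    return comps, base


def _occupied_centroid(grid: DensityGrid) -> np.ndarray:
    occ = grid.occupied_indices()
    if len(occ) == 0:
        raise ValueError("grid has no occupied voxels")
    return grid.voxel_coords(occ).mean(axis=0)


def _pullback_coords(ref: DensityGrid, query: DensityGrid,
                     transform: RigidTransform) -> list[np.ndarray]:
    """Fractional query-grid indices of every reference node under T^-1."""
    nx, ny, nz = ref.dims
    I, J, K = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    P = ref.origin + np.stack([I, J, K], axis=-1) * ref.spacing
    Q = (P - transform.pivot - transform.translation) @ transform.rotation \
        + transform.pivot
    return [(Q[..., a] - query.origin[a]) / query.spacing[a] for a in range(3)]


def cc_score(ref: DensityGrid, query: DensityGrid, transform: RigidTransform,
             ref_mask: np.ndarray | None = None,
             query_mask: np.ndarray | None = None) -> float:
    """Cross-correlation of two contoured maps under a rigid transform.

    Means and denominator sums of squares are taken over each map's own
    above-contour voxels; the numerator runs over the overlap (reference
    nodes occupied in both maps after superposition).  Occupancy masks
    can be supplied explicitly (used by the Laplacian-CC variant, where
    the scored values are filtered but occupancy still follows the
    original contour).  Returns a value in [-1, 1].
    """
    u_mask = ref.occupied_mask if ref_mask is None else ref_mask
    v_mask = query.occupied_mask if query_mask is None else query_mask
    if not np.any(u_mask) or not np.any(v_mask):
        raise ValueError("both maps need occupied voxels")
    u = ref.values
    v = query.values
    u_bar = u[u_mask].mean()
    v_bar = v[v_mask].mean()
    du2 = float(np.sum((u[u_mask] - u_bar) ** 2))
    dv2 = float(np.sum((v[v_mask] - v_bar) ** 2))
    if du2 <= 0 or dv2 <= 0:
        raise ValueError("zero density variance; CC undefined")
    coords = _pullback_coords(ref, query, transform)
    v_t = ndimage.map_coordinates(v, coords, order=1, mode="constant")
    m_t = ndimage.map_coordinates(v_mask.astype(float), coords, order=1,
                                  mode="constant")
    overlap = u_mask & (m_t >= 0.5)
    num = float(np.sum((u[overlap] - u_bar) * (v_t[overlap] - v_bar)))
    return num / math.sqrt(du2 * dv2)


def _rotation_lattice(grid: DensityGrid, R: np.ndarray, c: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Output lattice (origin, dims) covering the rotated occupied box."""
    occ = grid.occupied_indices()
    corners = grid.voxel_coords(np.stack(np.meshgrid(
        *[(occ[:, a].min(), occ[:, a].max()) for a in range(3)],
        indexing="ij"), axis=-1).reshape(-1, 3))
    rc = (corners - c) @ R.T + c
    lo = rc.min(axis=0) - grid.spacing
    hi = rc.max(axis=0) + grid.spacing
    n = np.floor((hi - lo) / grid.spacing + 1e-9).astype(int) + 1
    return lo, n


def _rotate_values(values: np.ndarray, grid: DensityGrid, R: np.ndarray,
                   c: np.ndarray, lo: np.ndarray, n: np.ndarray) -> np.ndarray:
    axes = [lo[a] + grid.spacing[a] * np.arange(n[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    Q = (P - c) @ R + c          # inverse rotation pull-back
    coords = [(Q[..., a] - grid.origin[a]) / grid.spacing[a] for a in range(3)]
    return ndimage.map_coordinates(values, coords, order=1, mode="constant")


def _axis_rotation(axis: int, degrees: float) -> np.ndarray:
    vec = np.zeros(3)
    vec[axis] = math.radians(degrees)
    return Rotation.from_rotvec(vec).as_matrix()


@dataclass
class _Pose:
    rot_index: int
    rotation: np.ndarray
    score: float
    translation: np.ndarray


def search(ref, query, interval: float = 30.0, top_k: int = 10,
           score: str = "dot", refine_interval: float = 5.0,
           bandwidth: float = 8.0, full_output: bool = False):
    """Exhaustive rigid-body search maximizing the DOT score (or CC).

    Parameters
    ----------
    ref, query
        ``VectorField``s (DOT score) or contoured, resampled
        ``DensityGrid``s (any score; grids are vectorized on the fly for
        DOT).
    interval
        Coarse rotational sampling interval in degrees (default 30).
    top_k
        Number of ranked results to return.
    score
        ``"dot"``, ``"cc"``, or ``"lapcc"`` (CC after Laplacian filtering
        of both maps).
    refine_interval
        Step (degrees) of the local angular refinement applied to the ten
        best coarse poses; skipped when ``interval <= refine_interval``.
    full_output
        Also return the :class:`~vecmap.score_stats.ScoreDistribution` of
        per-rotation best scores (for Z-score computation).

    Returns
    -------
    list of :class:`AlignmentResult` ranked by score with deterministic
    tie-breaks (rotation index, then lexicographic translation); with
    ``full_output`` a ``(results, distribution)`` pair.
    """
    from .score_stats import ScoreDistribution

    if score not in ("dot", "cc", "lapcc"):
        raise ValueError(f"unknown score {score!r}")

    ref_grid = ref if isinstance(ref, DensityGrid) else None
    query_grid = query if isinstance(query, DensityGrid) else None

    if score == "dot":
        ref_field = ref if isinstance(ref, VectorField) else \
            compute_vector_field(ref, bandwidth)
        query_field = query if isinstance(query, VectorField) else \
            compute_vector_field(query, bandwidth)
        pivot = query_field.centroid()
        A, a_base = _rasterize(ref_field)

        def scan_rotation(R: np.ndarray) -> tuple[float, np.ndarray]:
            pos = (query_field.coords - pivot) @ R.T + pivot
            dirs = query_field.directions @ R.T
            B, b_base = _splat(pos, dirs, query_field.origin,
                               query_field.spacing)
            sc = _scan(A, a_base, B, b_base,
                       ref_field.origin - query_field.origin,
                       ref_field.spacing)
            return sc.best()
    else:
        if ref_grid is None or query_grid is None:
            raise ValueError("CC search needs DensityGrid inputs")
        ref_mask = ref_grid.occupied_mask
        query_mask = query_grid.occupied_mask
        if score == "lapcc":
            # score the edge-filtered values, keep the contour occupancy
            ref_vals = np.where(ref_mask, laplacian_filter(ref_grid).values, 0.0)
            query_vals = np.where(query_mask,
                                  laplacian_filter(query_grid).values, 0.0)
        else:
            ref_vals = np.where(ref_mask, ref_grid.values, 0.0)
            query_vals = np.where(query_mask, query_grid.values, 0.0)
        pivot = _occupied_centroid(query_grid)
        u_bar = ref_vals[ref_mask].mean()
        du2 = float(np.sum((ref_vals[ref_mask] - u_bar) ** 2))
        if du2 <= 0:
            raise ValueError("zero density variance; CC undefined")
        A = np.where(ref_mask, ref_vals - u_bar, 0.0)[None]

        def scan_rotation(R: np.ndarray) -> tuple[float, np.ndarray]:
            lo, n = _rotation_lattice(query_grid, R, pivot)
            vrot = _rotate_values(query_vals, query_grid, R, pivot, lo, n)
            mrot = _rotate_values(query_mask.astype(float), query_grid, R,
                                  pivot, lo, n) >= 0.5
            if not np.any(mrot):
                return -np.inf, np.zeros(3)
            v_bar = vrot[mrot].mean()
            dv2 = float(np.sum((vrot[mrot] - v_bar) ** 2))
            if dv2 <= 0:
                return -np.inf, np.zeros(3)
            B = np.where(mrot, vrot - v_bar, 0.0)[None]
            sc = _scan(A, np.zeros(3, dtype=int), B, np.zeros(3, dtype=int),
                       ref_grid.origin - lo, ref_grid.spacing)
            sc.scores = sc.scores / math.sqrt(du2 * dv2)
            return sc.best()

    rotations = enumerate_rotations(interval)
    per_rotation_best = np.empty(len(rotations))
    poses: list[_Pose] = []
    for i, R in enumerate(rotations):
        best_score, best_t = scan_rotation(R)
        per_rotation_best[i] = best_score
        poses.append(_Pose(i, R, best_score, best_t))

    # ten best coarse poses, deterministic tie-break by rotation index
    order = sorted(range(len(poses)),
                   key=lambda i: (-poses[i].score, poses[i].rot_index))
    candidates = [poses[i] for i in order[:max(top_k, 10)]]

    if interval > refine_interval:
        deltas = [d for d in np.arange(-interval,
                                       interval + refine_interval / 2,
                                       refine_interval) if d != 0.0]
        for pose in candidates:
            # two greedy passes of independent per-axis scans
            for _ in range(2):
                for axis in range(3):
                    best = (pose.score, pose.rotation, pose.translation)
                    for d in deltas:
                        Rc = _axis_rotation(axis, d) @ pose.rotation
                        s, t = scan_rotation(Rc)
                        if s > best[0] + 1e-9:
                            best = (s, Rc, t)
                    pose.score, pose.rotation, pose.translation = best

    candidates.sort(key=lambda p: (-p.score, p.rot_index,
                                   tuple(np.round(p.translation, 6))))

    results: list[AlignmentResult] = []
    for rank, pose in enumerate(candidates[:top_k], start=1):
        transform = RigidTransform(pose.rotation, pose.translation, pivot)
        if score == "dot":
            dot, overlap = dot_score_direct(ref_field, query_field, transform)
            cc = math.nan
            if ref_grid is not None and query_grid is not None:
                cc = cc_score(ref_grid, query_grid, transform)
            results.append(AlignmentResult(transform, dot, cc, overlap, rank))
        else:
            ref_for_cc = DensityGrid(ref_vals, ref_grid.spacing,
                                     ref_grid.origin)
            query_for_cc = DensityGrid(query_vals, query_grid.spacing,
                                       query_grid.origin)
            cc = cc_score(ref_for_cc, query_for_cc, transform,
                          ref_mask=ref_mask, query_mask=query_mask)
            results.append(AlignmentResult(transform, math.nan, cc, 0, rank))

    if full_output:
        refined_best = max(p.score for p in candidates)
        dist = ScoreDistribution(per_rotation_best=per_rotation_best,
                                 refined_best=float(refined_best))
        return results, dist
    return results
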