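"""Synthetic density maps and planted-transform fixtures.

Simulated maps place an isotropic Gaussian at each atom with standard
deviation 0.225 x resolution and unit peak amplitude (the convention of
Chimera's molmap), contoured at 0.2 by default.  Procedural toy volumes
(an L-shaped solid, a helical tube, a two-blob dumbbell) provide
asymmetric densities with no rotational self-symmetry, and
``plant_transform`` produces a rigidly moved copy of a map together with
the exact ground-truth transform for recovery tests.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .align import RigidTransform
from .map_io import AtomicModel, DensityGrid

__all__ = ["simulate_map", "make_toy_model", "make_toy_volume",
           "plant_transform", "GAUSSIAN_SD_FACTOR"]

#: Gaussian sd per Angstrom of resolution (molmap convention)
GAUSSIAN_SD_FACTOR = 0.225
#: default contour level for simulated maps
SIMULATED_CONTOUR = 0.2


def simulate_map(model: AtomicModel, resolution: float, spacing: float,
                 origin: np.ndarray | None = None,
                 dims: tuple[int, int, int] | None = None) -> DensityGrid:
    """Simulate a density map from atomic coordinates.

    Each atom contributes ``exp(-d^2 / (2 sd^2))`` with
    ``sd = 0.225 * resolution`` (unit peak amplitude; Gaussians are
    truncated at 5 sd).  By default the lattice covers the atoms plus a
    ``max(3 sd, spacing)`` margin; pass ``origin``/``dims`` to evaluate
    on a fixed lattice instead (e.g. to exploit linearity over chains).
    """
    if resolution <= 0 or spacing <= 0:
        raise ValueError("resolution and spacing must be positive")
    sd = GAUSSIAN_SD_FACTOR * resolution
    pos = model.positions
    if origin is None:
        pad = max(3.0 * sd, spacing)
        origin = pos.min(axis=0) - pad
    origin = np.asarray(origin, dtype=np.float64)
    if dims is None:
        pad = max(3.0 * sd, spacing)
        hi = pos.max(axis=0) + pad
        dims = tuple(np.floor((hi - origin) / spacing + 1e-9).astype(int) + 1)
    values = np.zeros(dims)
    cutoff = 5.0 * sd
    rvox = int(np.ceil(cutoff / spacing))
    for p in pos:
        center = (p - origin) / spacing
        lo = np.maximum(np.floor(center).astype(int) - rvox, 0)
        hi = np.minimum(np.floor(center).astype(int) + rvox + 1, dims)
        if np.any(lo >= hi):
            continue
        ax = [np.arange(lo[a], hi[a]) * spacing + origin[a] - p[a]
              for a in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        d2 = X ** 2 + Y ** 2 + Z ** 2
        blob = np.exp(-d2 / (2.0 * sd * sd))
        blob[d2 > cutoff ** 2] = 0.0
        values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += blob
    return DensityGrid(values=values, spacing=np.full(3, float(spacing)),
                       origin=origin, contour=SIMULATED_CONTOUR)


def make_toy_model(n_residues: int = 150, seed: int = 3) -> AtomicModel:
    """Synthetic C-alpha trace: a smooth persistent random walk.

    Consecutive pseudo-residues sit 3.8 Angstrom apart with correlated
    step directions, giving a compact, chain-like, asymmetric shape
    suitable for simulating protein-sized density maps without any
    external coordinate file.  Fully determined by ``seed``.
    """
    if n_residues < 2:
        raise ValueError("need at least two residues")
    rng = np.random.default_rng(seed)
    pos = [np.zeros(3)]
    step = np.array([1.0, 0.0, 0.0])
    for _ in range(n_residues - 1):
        step = step + 0.8 * rng.normal(size=3)
        step /= np.linalg.norm(step)
        pos.append(pos[-1] + 3.8 * step)
    pos = np.asarray(pos)
    n = len(pos)
    return AtomicModel(np.array(["A"] * n), np.arange(1, n + 1),
                       np.array(["CA"] * n), np.array(["C"] * n),
                       pos, np.ones(n))


def make_toy_volume(kind: str = "L-shape", size: int = 16, seed: int = 0,
                    spacing: float = 7.0, noise_sd: float = 0.0) -> DensityGrid:
    """Deterministic procedural density with known asymmetry.

    Parameters
    ----------
    kind
        ``"L-shape"`` (three mutually unequal solid arms, no rotational
        self-symmetry), ``"helix-tube"`` (Gaussian beads on a helix), or
        ``"two-blob"`` (unequal dumbbell).
    size
        Cubic grid extent in voxels (>= 8).
    seed
        Seeds the optional additive Gaussian noise of ``noise_sd``.
    spacing
        Voxel size in Angstrom (default 7, the working spacing).

    The density is smoothed, peak-normalized to 1, and contoured at 0.2.
    """
    if size < 8:
        raise ValueError("toy volumes need size >= 8")
    rng = np.random.default_rng(seed)
    v = np.zeros((size, size, size))
    q = size // 4
    if kind == "L-shape":
        # three arms of different lengths and thicknesses from one corner
        v[q:size - q, q:q + 2, q:q + 2] = 1.0                 # long x arm
        v[q:q + 2, q:size - 2 * q, q:q + 3] = 1.0             # medium y arm
        v[q:q + 3, q:q + 2, q:q + max(3, size // 3)] = 1.0    # short fat z arm
        v[size - q - 2:size - q, q:q + 2, q:q + 4] = 1.0      # asymmetric knob
    elif kind == "helix-tube":
        t = np.linspace(0, 4 * np.pi, 60)
        radius = size / 5.0
        cx = size / 2 + radius * np.cos(t)
        cy = size / 2 + radius * np.sin(t)
        cz = q + (size - 2 * q) * t / t.max()
        for x, y, z in zip(cx, cy, cz):
            i, j, k = int(round(x)), int(round(y)), int(round(z))
            if 0 <= i < size and 0 <= j < size and 0 <= k < size:
                v[i, j, k] = 1.0
    elif kind == "two-blob":
        ax = np.arange(size)
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        c1 = np.array([q, size / 2, size / 2])
        c2 = np.array([size - q, size / 2, size / 2])
        v = np.exp(-((X - c1[0]) ** 2 + (Y - c1[1]) ** 2 + (Z - c1[2]) ** 2)
                   / (2 * (size / 10) ** 2))
        v += 0.6 * np.exp(-((X - c2[0]) ** 2 + (Y - c2[1]) ** 2
                            + (Z - c2[2]) ** 2) / (2 * (size / 14) ** 2))
    else:
        raise ValueError(f"unknown toy kind {kind!r}")
    v = ndimage.gaussian_filter(v, sigma=1.0)
    v /= v.max()
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, v.shape)
    return DensityGrid(values=v, spacing=np.full(3, float(spacing)),
                       origin=np.zeros(3), contour=0.2)


def plant_transform(grid: DensityGrid, rotation: tuple[float, float, float],
                    translation: tuple[float, float, float],
                    noise_sd: float = 0.0, seed: int = 0
                    ) -> tuple[DensityGrid, RigidTransform]:
    """Rigidly move a map and return it with the ground-truth transform.

    ``rotation`` is a z-y-z Euler triplet in degrees; ``translation`` is in
    Angstrom.  The pivot is the occupied-volume centroid snapped to the
    nearest lattice node, so pure lattice rotations (multiples of 90
    degrees) combined with whole-voxel shifts are exact voxel
    permutations.  Densities are resampled with trilinear interpolation
    onto a lattice covering the moved volume; optional additive Gaussian
    noise is seeded.
    """
    R = Rotation.from_euler("ZYZ", rotation, degrees=True).as_matrix()
    t = np.asarray(translation, dtype=np.float64)
    occ = grid.occupied_indices()
    if len(occ) == 0:
        raise ValueError("grid has no occupied voxels")
    c = grid.voxel_coords(occ).mean(axis=0)
    c = grid.origin + np.rint((c - grid.origin) / grid.spacing) * grid.spacing
    transform = RigidTransform(R, t, pivot=c)

    corners = grid.voxel_coords(np.stack(np.meshgrid(
        *[(occ[:, a].min(), occ[:, a].max()) for a in range(3)],
        indexing="ij"), axis=-1).reshape(-1, 3))
    moved = transform.apply(corners)
    pad = 2.0 * grid.spacing
    lo = moved.min(axis=0) - pad
    hi = moved.max(axis=0) + pad
    # keep the output nodes on the input lattice so exact cases stay exact
    lo = grid.origin + np.floor((lo - grid.origin) / grid.spacing) * grid.spacing
    n = np.floor((hi - lo) / grid.spacing + 1e-9).astype(int) + 1

    axes = [lo[a] + grid.spacing[a] * np.arange(n[a]) for a in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)
    Q = (P - c - t) @ R + c      # inverse transform pull-back
    coords = [(Q[..., a] - grid.origin[a]) / grid.spacing[a] for a in range(3)]
    values = ndimage.map_coordinates(grid.values, coords, order=1,
                                     mode="constant")
    if grid.contour is not None and not np.any(values >= grid.contour):
        raise ValueError("transform moved all density outside the padded box")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, values.shape)
    out = DensityGrid(values=values, spacing=grid.spacing.copy(), origin=lo,
                      contour=grid.contour)
    return out, transform
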