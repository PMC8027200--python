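"""Unit gradient-vector field representation of a density map.

Each occupied voxel x_i carries a unit vector pointing toward y_i, the
kernel- and density-weighted mean position of its occupied neighborhood
(one mean-shift step):

    y_i = sum_n k(x_i - x_n) Phi(x_n) x_n / sum_n k(x_i - x_n) Phi(x_n)

with the Gaussian kernel k(p) = exp(-1.5 |p/sigma|^2), truncated at 2 sigma.
The bandwidth sigma defaults to 8 Angstrom.  Voxels where |y_i - x_i| is
numerically zero (local maxima, perfectly symmetric neighborhoods) carry no
direction and are dropped from the field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .map_io import DensityGrid
from .preprocess import DEFAULT_BANDWIDTH, gaussian_kernel_lattice

__all__ = ["VectorField", "mean_shift_target", "compute_vector_field"]


@dataclass
class VectorField:
    """Occupied grid positions, each carrying a unit gradient vector."""

    indices: np.ndarray        # (N, 3) integer voxel indices
    directions: np.ndarray     # (N, 3) unit vectors
    spacing: np.ndarray        # voxel edge lengths in Angstrom
    origin: np.ndarray         # Cartesian position of voxel (0,0,0), Angstrom
    n_dropped: int = 0         # occupied voxels dropped for |y - x| ~ 0

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64).reshape(-1, 3)
        self.directions = np.asarray(self.directions, dtype=np.float64).reshape(-1, 3)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if len(self.indices) != len(self.directions):
            raise ValueError("positions and directions must have equal length")
        if len(self.indices):
            norms = np.linalg.norm(self.directions, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValueError("directions must be unit vectors")
            uniq = np.unique(self.indices, axis=0)
            if len(uniq) != len(self.indices):
                raise ValueError("positions must be unique")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def count(self) -> int:
        return len(self.indices)

    @property
    def coords(self) -> np.ndarray:
        """Cartesian coordinates (Angstrom) of the vector positions."""
        return self.origin + self.indices * self.spacing

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def save_tsv(self, path) -> None:
        """Write as a plain-text table with a JSON header line."""
        import json
        header = json.dumps({"spacing": self.spacing.tolist(),
                             "origin": self.origin.tolist(),
                             "n": int(self.count), "n_dropped": self.n_dropped})
        data = np.hstack([self.coords, self.directions])
        with open(path, "w") as fh:
            fh.write(f"#VFIELD {header}\n")
            fh.write("#x\ty\tz\tux\tuy\tuz\n")
            for row in data:
                fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def load_tsv(cls, path) -> "VectorField":
        import json
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#VFIELD "):
                raise ValueError("not a vector-field table")
            meta = json.loads(first[len("#VFIELD "):])
            rows = [list(map(float, ln.split("\t"))) for ln in fh
                    if ln.strip() and not ln.startswith("#")]
        data = np.asarray(rows, dtype=np.float64).reshape(-1, 6)
        spacing = np.asarray(meta["spacing"])
        origin = np.asarray(meta["origin"])
        idx = np.rint((data[:, :3] - origin) / spacing).astype(np.int64)
        dirs = data[:, 3:]
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        return cls(idx, dirs, spacing, origin, n_dropped=meta.get("n_dropped", 0))


def mean_shift_target(grid: DensityGrid, position, bandwidth: float = DEFAULT_BANDWIDTH
                      ) -> np.ndarray:
    """One mean-shift step from the voxel at integer index ``position``.

    Returns the Cartesian coordinate y_i (Angstrom) of the kernel- and
    density-weighted mean over occupied voxels within the truncation
    radius.  Direct (loop-free but unconvolved) evaluation; the field-wide
    convolution path in :func:`compute_vector_field` must agree with it.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    position = np.asarray(position, dtype=np.int64).reshape(3)
    mask = grid.occupied_mask
    if not mask[tuple(position)]:
        raise ValueError("mean-shift start must be an occupied voxel")
    occ = np.argwhere(mask)
    disp = (occ - position) * grid.spacing
    dist2 = np.sum(disp ** 2, axis=1)
    cutoff2 = (2.0 * bandwidth) ** 2 * (1 + 1e-12)
    near = dist2 <= cutoff2
    k = np.exp(-1.5 * dist2[near] / bandwidth ** 2)
    phi = grid.values[tuple(occ[near].T)]
    w = k * phi
    denom = w.sum()
    if denom <= 0:
        raise ValueError("degenerate mean-shift point: no occupied neighbors")
    x = grid.voxel_coords(occ[near])
    return (w[:, None] * x).sum(axis=0) / denom


def compute_vector_field(grid: DensityGrid, bandwidth: float = DEFAULT_BANDWIDTH
                         ) -> VectorField:
    """Unit vector (y_i - x_i)/|y_i - x_i| at every occupied voxel.

    The grid should already be resampled to the working spacing and
    contoured; sub-threshold voxels contribute zero weight.  Voxels whose
    mean-shift displacement is below ``1e-6 * min(spacing)`` are dropped
    and counted in ``n_dropped``.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    mask = grid.occupied_mask
    if not np.any(mask):
        raise ValueError("no occupied voxels; contour the grid first")
    phi = np.where(mask, grid.values, 0.0)
    weights, offsets, _ = gaussian_kernel_lattice(grid.spacing, bandwidth)

    den = ndimage.correlate(phi, weights, mode="constant", cval=0.0)
    disp = np.empty(grid.dims + (3,))
    for axis in range(3):
        kd = weights * offsets[axis] * grid.spacing[axis]
        disp[..., axis] = ndimage.correlate(phi, kd, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp /= den[..., None]

    idx = np.argwhere(mask)
    d = disp[mask]
    norm = np.linalg.norm(d, axis=1)
    eps = 1e-6 * float(grid.spacing.min())
    keep = norm > eps
    directions = d[keep] / norm[keep, None]
    return VectorField(indices=idx[keep], directions=directions,
                       spacing=grid.spacing.copy(), origin=grid.origin.copy(),
                       n_dropped=int((~keep).sum()))
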