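"""Reading and writing density maps (MRC/CCP4) and atomic models (PDB).

Internal conventions
--------------------
* ``DensityGrid.values`` is always indexed ``[ix, iy, iz]`` — axis 0 runs
  along Cartesian x, axis 1 along y, axis 2 along z.  Header axis
  permutations (``MAPC/MAPR/MAPS``) are resolved at read time.
* Voxel centers carry density: voxel ``(i, j, k)`` sits at
  ``origin + (i, j, k) * spacing``.
* The origin is taken from the MRC ``ORIGIN`` record when present; when all
  three words are zero it falls back to ``N*START * spacing``, matching
  common EMDB deposition practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = ["DensityGrid", "AtomicModel", "read_map", "write_map", "read_pdb"]


@dataclass
class DensityGrid:
    """A 3D scalar density lattice with voxel spacing, origin, and contour.

    Parameters
    ----------
    values
        Density values indexed ``[ix, iy, iz]`` (arbitrary map units).
    spacing
        Voxel edge lengths in Angstrom, one per axis.
    origin
        Cartesian position in Angstrom of voxel ``(0, 0, 0)``.
    contour
        Density threshold defining the occupied volume (the
        author-recommended contour level for EMDB entries), or ``None``
        while not yet set.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    contour: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.values.ndim != 3:
            raise ValueError("density values must be a 3D array")
        if not np.all(self.spacing > 0):
            raise ValueError("all spacing components must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def occupied_mask(self) -> np.ndarray:
        """Boolean mask of occupied voxels (density >= contour, or > 0)."""
        if self.contour is not None:
            return self.values >= self.contour
        return self.values > 0

    def voxel_coords(self, indices: np.ndarray) -> np.ndarray:
        """Cartesian coordinates (Angstrom) of integer voxel indices."""
        return self.origin + np.asarray(indices, dtype=np.float64) * self.spacing

    def occupied_indices(self) -> np.ndarray:
        """Integer index triplets of occupied voxels, C-order."""
        return np.argwhere(self.occupied_mask)

    def copy(self) -> "DensityGrid":
        return replace(self, values=self.values.copy(), spacing=self.spacing.copy(),
                       origin=self.origin.copy())


@dataclass
class AtomicModel:
    """A minimal atomic model: per-atom metadata plus Cartesian coordinates."""

    chains: np.ndarray          # chain identifier per atom
    residues: np.ndarray        # residue sequence number per atom
    names: np.ndarray           # atom name per atom
    elements: np.ndarray        # element symbol per atom
    positions: np.ndarray       # (n, 3) Cartesian coordinates in Angstrom
    weights: np.ndarray         # per-atom mass (or unit weight)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        if len(self.positions) == 0:
            raise ValueError("atomic model must contain at least one atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions must be finite")
        self.weights = np.asarray(self.weights, dtype=np.float64).reshape(-1)

    def __len__(self) -> int:
        return len(self.positions)

    def select_chain(self, chain_id: str) -> "AtomicModel":
        keep = self.chains == chain_id
        if not np.any(keep):
            raise ValueError(f"no atoms in chain {chain_id!r}")
        return AtomicModel(self.chains[keep], self.residues[keep], self.names[keep],
                           self.elements[keep], self.positions[keep], self.weights[keep])

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)


def _check_orthogonal(angles: tuple[float, float, float]) -> None:
    if not np.allclose(angles, 90.0, atol=1e-3):
        raise ValueError(
            f"non-orthogonal cell (angles {angles}); only orthogonal maps are supported"
        )


def read_map(path: str | Path, contour: float | None = None) -> DensityGrid:
    """Read an MRC/CCP4 density map into the canonical x,y,z axis order.

    Axis permutations declared by the MAPC/MAPR/MAPS header words are
    undone, so ``values[ix, iy, iz]`` always follows Cartesian axes.
    Non-orthogonal cells are rejected.
    """
    ccp4 = gemmi.read_ccp4_map(str(path))
    cell = ccp4.grid.unit_cell
    _check_orthogonal((cell.alpha, cell.beta, cell.gamma))

    # axis order on disk: array axes are (column, row, section)
    mapcrs = [ccp4.header_i32(w) for w in (17, 18, 19)]
    if sorted(mapcrs) != [1, 2, 3]:
        raise ValueError(f"invalid MAPC/MAPR/MAPS header words {mapcrs}")
    raw = np.array(ccp4.grid, copy=True)

    # sampling counts along the crystal x,y,z axes
    m_xyz = np.array([ccp4.header_i32(w) for w in (8, 9, 10)], dtype=float)
    if np.any(m_xyz <= 0):
        raise ValueError("invalid sampling counts in header")
    spacing = np.array([cell.a, cell.b, cell.c]) / m_xyz
    if np.any(spacing <= 0):
        raise ValueError("zero voxel spacing")

    values = np.transpose(raw, axes=[mapcrs.index(1), mapcrs.index(2), mapcrs.index(3)])

    # N*START words are stored in file (column/row/section) order
    nstart_file = [ccp4.header_i32(w) for w in (5, 6, 7)]
    nstart = np.empty(3)
    for file_axis, crystal_axis in enumerate(mapcrs):
        nstart[crystal_axis - 1] = nstart_file[file_axis]

    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)], dtype=float)
    if np.all(origin == 0.0):
        origin = nstart * spacing

    return DensityGrid(values=values, spacing=spacing, origin=origin, contour=contour)


def write_map(grid: DensityGrid, path: str | Path) -> None:
    """Write a density grid as an MRC (mode 2, float32) map.

    The canonical axis order is used on disk (MAPC/MAPR/MAPS = 1,2,3) and
    the origin is stored in the ORIGIN header words, so the file
    round-trips through :func:`read_map` at float32 precision.
    """
    fgrid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    nx, ny, nz = grid.dims
    sx, sy, sz = grid.spacing
    fgrid.unit_cell = gemmi.UnitCell(nx * sx, ny * sy, nz * sz, 90.0, 90.0, 90.0)
    fgrid.spacegroup = gemmi.SpaceGroup("P1")
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = fgrid
    ccp4.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.write_ccp4_map(str(path))


def read_pdb(path: str | Path, chain: str | None = None) -> AtomicModel:
    """Parse ATOM/HETATM records from a PDB file into an :class:`AtomicModel`.

    Atoms from the first model are used; ``chain`` restricts the selection
    to a single chain identifier.
    """
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise ValueError(f"no models parsed from {path}")
    chains, residues, names, elements, positions, weights = [], [], [], [], [], []
    for ch in structure[0]:
        if chain is not None and ch.name != chain:
            continue
        for res in ch:
            for atom in res:
                chains.append(ch.name)
                residues.append(res.seqid.num)
                names.append(atom.name)
                elements.append(atom.element.name)
                positions.append([atom.pos.x, atom.pos.y, atom.pos.z])
                weights.append(atom.element.weight if atom.element.weight > 0 else 1.0)
    if not positions:
        raise ValueError(f"no atoms parsed from {path}" +
                         (f" (chain {chain!r})" if chain else ""))
    return AtomicModel(np.array(chains), np.array(residues), np.array(names),
                       np.array(elements), np.array(positions), np.array(weights))
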