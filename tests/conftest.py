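import numpy as np
import pytest

import vecmap


@pytest.fixture(scope="session")
def l_shape():
    """Contoured asymmetric toy map at the working 7 A spacing."""
    return vecmap.apply_contour(vecmap.make_toy_volume("L-shape", 16, 0), 0.2)


@pytest.fixture(scope="session")
def l_shape_field(l_shape):
    return vecmap.compute_vector_field(l_shape)


@pytest.fixture(scope="session")
def protein_map():
    """Simulated-protein map, resampled to 7 A and contoured at 0.2."""
    model = vecmap.make_toy_model(150, seed=3)
    sim = vecmap.simulate_map(model, resolution=10.0, spacing=3.0)
    return vecmap.apply_contour(vecmap.resample(sim, 7.0), 0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_vector_field(rng, n, box, spacing=7.0, origin=(0.0, 0.0, 0.0)):
    """Sparse random unit-vector field on an integer lattice."""
    idx = np.unique(rng.integers(0, box, size=(n * 2, 3)), axis=0)[:n]
    dirs = rng.normal(size=(len(idx), 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return vecmap.VectorField(idx, dirs, np.full(3, spacing), np.asarray(origin))


def pairwise_dot_lattice(ref, query):
    """Independent DOT-score oracle: accumulate every vector pair into the
    translation bin given by its index difference."""
    table = {}
    for ia, da in zip(ref.indices, ref.directions):
        for ib, db in zip(query.indices, query.directions):
            key = tuple(ia - ib)
            table[key] = table.get(key, 0.0) + float(da @ db)
    return table


def lattice_rotation_matrices():
    """The 24 proper rotations of the cube, as exact integer matrices."""
    mats = []
    for perm in ([0, 1, 2], [0, 2, 1], [1, 0, 2], [1, 2, 0], [2, 0, 1],
                 [2, 1, 0]):
        for signs in np.ndindex(2, 2, 2):
            R = np.zeros((3, 3))
            for row, (p, s) in enumerate(zip(perm, signs)):
                R[row, p] = 1.0 - 2.0 * s
            if np.linalg.det(R) > 0:
                mats.append(R)
    return mats


def rotate_grid_lattice(grid, R):
    """Exactly rotate a cubic DensityGrid by a lattice rotation about its
    box center (pure voxel permutation)."""
    n = grid.dims[0]
    assert grid.dims == (n, n, n)
    ctr = (n - 1) / 2.0
    idx = np.indices(grid.dims).reshape(3, -1).T
    new_idx = np.rint((idx - ctr) @ R.T + ctr).astype(int)
    values = np.zeros_like(grid.values)
    values[new_idx[:, 0], new_idx[:, 1], new_idx[:, 2]] = \
        grid.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    return vecmap.DensityGrid(values, grid.spacing.copy(), grid.origin.copy(),
                              grid.contour)
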