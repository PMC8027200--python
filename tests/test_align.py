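"""Rotation enumeration, field rotation, DOT/CC scoring, and the search."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import vecmap
from vecmap.align import (RigidTransform, cc_score, dot_score_direct,
                          enumerate_rotations, fft_translation_scan,
                          rotate_field, search)

from conftest import (lattice_rotation_matrices, pairwise_dot_lattice,
                      random_vector_field, rotate_grid_lattice)


def _geodesic(Ra, Rb):
    cos = (np.trace(Ra.T @ Rb) - 1) / 2
    return math.degrees(math.acos(min(1.0, max(-1.0, cos))))


class TestEnumerateRotations:
    def test_interval_90_gives_cube_group(self):
        rots = enumerate_rotations(90)
        cube = lattice_rotation_matrices()
        assert len(rots) == 24
        for R in rots:
            assert min(_geodesic(R, C) for C in cube) < 1e-5

    def test_interval_180_gives_identity_and_flips(self):
        rots = enumerate_rotations(180)
        assert len(rots) == 4
        expected = [np.eye(3)] + [Rotation.from_rotvec(np.pi * np.eye(3)[a]
                                                       ).as_matrix()
                                  for a in range(3)]
        for E in expected:
            assert min(_geodesic(R, E) for R in rots) < 1e-5

    def test_interval_30_proper_superset_of_cube(self):
        rots = enumerate_rotations(30)
        for R in rots:
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0)
        for C in lattice_rotation_matrices():
            assert min(_geodesic(R, C) for R in rots) < 1e-5

    def test_pairwise_separation(self):
        rots = enumerate_rotations(60)
        for i, Ra in enumerate(rots):
            for Rb in rots[i + 1:]:
                assert _geodesic(Ra, Rb) >= 30 - 1e-6

    @pytest.mark.parametrize("bad", [0, -30, 7, 200, 361])
    def test_invalid_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            enumerate_rotations(bad)

    def test_identity_first(self):
        assert np.allclose(enumerate_rotations(30)[0], np.eye(3))


class TestRotateField:
    def test_identity_rotation_is_noop(self, l_shape_field):
        out = rotate_field(l_shape_field, np.eye(3))
        np.testing.assert_array_equal(
            np.sort(out.indices, axis=0), np.sort(l_shape_field.indices, axis=0))
        assert out.count == l_shape_field.count

    def test_lattice_rotation_permutes_exactly(self, rng):
        # full cubic block: its centroid is the box center, so a 90-degree
        # rotation about z maps lattice nodes onto lattice nodes exactly
        idx = np.indices((4, 4, 4)).reshape(3, -1).T
        dirs = rng.normal(size=(len(idx), 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        f = vecmap.VectorField(idx, dirs, np.full(3, 7.0), np.zeros(3))
        Rz = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        out = rotate_field(f, Rz)
        assert out.count == f.count
        lut = {tuple(i): d for i, d in zip(out.indices, out.directions)}
        ctr = 1.5
        for i, d in zip(f.indices, f.directions):
            tgt = tuple(np.rint((i - ctr) @ Rz.T + ctr).astype(int))
            np.testing.assert_allclose(lut[tgt], Rz @ d, atol=1e-12)

    def test_rotation_round_trip_recovers_directions(self, l_shape_field):
        # modest rotation: loss comes only from lattice snapping; large
        # rotations also merge colliding vectors and recover fewer
        R = Rotation.from_euler("ZYZ", [8, 4, 0], degrees=True).as_matrix()
        back = rotate_field(rotate_field(l_shape_field, R), R.T)
        lut = {tuple(i): d for i, d in
               zip(l_shape_field.indices, l_shape_field.directions)}
        recovered = 0
        for i, d in zip(back.indices, back.directions):
            orig = lut.get(tuple(i))
            if orig is not None and np.linalg.norm(orig - d) < 1e-6:
                recovered += 1
        assert recovered >= 0.95 * l_shape_field.count


class TestDotScoreDirect:
    def test_self_identity_scores_count(self, l_shape_field):
        s, overlap = dot_score_direct(l_shape_field, l_shape_field,
                                      RigidTransform.identity())
        assert s == pytest.approx(l_shape_field.count)
        assert overlap == l_shape_field.count

    def test_negated_field_scores_minus_count(self, l_shape_field):
        neg = vecmap.VectorField(l_shape_field.indices.copy(),
                                 -l_shape_field.directions,
                                 l_shape_field.spacing, l_shape_field.origin)
        s, overlap = dot_score_direct(l_shape_field, neg,
                                      RigidTransform.identity())
        assert s == pytest.approx(-l_shape_field.count)
        assert overlap == l_shape_field.count

    def test_score_bounded_by_overlap(self, rng):
        a = random_vector_field(rng, 60, 10)
        b = random_vector_field(rng, 50, 10)
        s, overlap = dot_score_direct(a, b, RigidTransform.identity())
        assert -overlap - 1e-9 <= s <= overlap + 1e-9
        assert overlap <= min(a.count, b.count)


class TestFFTTranslationScan:
    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            a = random_vector_field(rng, 50, 14)
            b = random_vector_field(rng, 40, 10)
            scan = fft_translation_scan(a, b)
            table = pairwise_dot_lattice(a, b)
            for key, expected in table.items():
                li = tuple(np.array(key) - scan.offset0)
                assert scan.scores[li] == pytest.approx(expected, abs=1e-6)
            # translations with no pair at all are (numerically) zero
            assert np.sum(np.abs(scan.scores) > 1e-6) <= len(table)

    def test_self_scan_peaks_at_zero_shift(self, l_shape_field):
        scan = fft_translation_scan(l_shape_field, l_shape_field)
        score, t = scan.best()
        assert score == pytest.approx(l_shape_field.count, abs=1e-6)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_disjoint_support_scores_zero(self, rng):
        a = random_vector_field(rng, 20, 6)
        b = random_vector_field(rng, 20, 6)
        scan = fft_translation_scan(a, b)
        corner = scan.scores[0, 0, 0]  # only one pair can overlap there
        assert abs(corner) <= 1.0 + 1e-9

    def test_empty_field_rejected(self, rng, l_shape_field):
        empty = vecmap.VectorField(np.empty((0, 3), dtype=int),
                                   np.empty((0, 3)), np.full(3, 7.0),
                                   np.zeros(3))
        with pytest.raises(ValueError, match="empty"):
            fft_translation_scan(l_shape_field, empty)


class TestCCScore:
    def test_self_identity_is_one(self, l_shape):
        assert cc_score(l_shape, l_shape, RigidTransform.identity()) == \
            pytest.approx(1.0, abs=1e-9)

    def test_negation_about_mean_is_minus_one(self, rng):
        v = rng.random((5, 5, 5))
        low = -1e30  # contour below all values: every voxel occupied
        a = vecmap.DensityGrid(v, np.full(3, 7.0), np.zeros(3), low)
        b = vecmap.DensityGrid(-v, np.full(3, 7.0), np.zeros(3), low)
        assert cc_score(a, b, RigidTransform.identity()) == \
            pytest.approx(-1.0, abs=1e-9)

    def test_matches_hand_evaluated_formula(self, rng):
        u = rng.random((4, 4, 4))
        v = rng.random((4, 4, 4))
        cu, cv = float(np.median(u)), float(np.median(v))
        a = vecmap.DensityGrid(u, np.full(3, 7.0), np.zeros(3), cu)
        b = vecmap.DensityGrid(v, np.full(3, 7.0), np.zeros(3), cv)
        got = cc_score(a, b, RigidTransform.identity())
        # arithmetic oracle, written out in full
        mu = u[u >= cu].mean()
        mv = v[v >= cv].mean()
        num = 0.0
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    if u[i, j, k] >= cu and v[i, j, k] >= cv:
                        num += (u[i, j, k] - mu) * (v[i, j, k] - mv)
        den = math.sqrt(np.sum((u[u >= cu] - mu) ** 2)) * \
            math.sqrt(np.sum((v[v >= cv] - mv) ** 2))
        assert got == pytest.approx(num / den, abs=1e-9)

    def test_zero_variance_errors(self):
        flat = vecmap.DensityGrid(np.ones((4, 4, 4)), np.full(3, 7.0),
                                  np.zeros(3), 0.5)
        with pytest.raises(ValueError, match="variance"):
            cc_score(flat, flat, RigidTransform.identity())


class TestSearch:
    def test_self_search_identity_rank_one(self, l_shape_field):
        res = search(l_shape_field, l_shape_field, interval=30)
        r1 = res[0]
        assert r1.rank == 1
        assert r1.transform.geodesic_angle_to(np.eye(3)) < 1e-9
        np.testing.assert_allclose(r1.transform.to_origin_form().translation,
                                   0.0, atol=1e-9)
        assert r1.dot_score == pytest.approx(l_shape_field.count)
        assert r1.overlap == l_shape_field.count

    def test_self_search_on_grids_reports_cc_one(self, l_shape):
        res = search(l_shape, l_shape, interval=90, refine_interval=90)
        assert res[0].cc == pytest.approx(1.0, abs=1e-6)
        assert res[0].dot_score == pytest.approx(
            vecmap.compute_vector_field(l_shape).count)

    def test_planted_sixty_degree_recovery(self, l_shape):
        moved, truth = vecmap.plant_transform(l_shape, (60, 0, 0),
                                              (14.0, -7.0, 7.0))
        res = search(moved, l_shape, interval=30)
        r1 = res[0]
        assert r1.transform.geodesic_angle_to(truth) <= 5.0 + 1e-6
        t_err = np.linalg.norm(r1.transform.apply(truth.pivot) -
                               truth.apply(truth.pivot))
        assert t_err <= 7.0
        n = vecmap.compute_vector_field(l_shape).count
        assert r1.dot_score >= 0.5 * n

    def test_lattice_planting_is_lossless(self, l_shape):
        moved, truth = vecmap.plant_transform(l_shape, (90, 0, 0),
                                              (14.0, -7.0, 21.0))
        res = search(moved, l_shape, interval=90, refine_interval=90)
        r1 = res[0]
        n = vecmap.compute_vector_field(l_shape).count
        assert r1.dot_score == pytest.approx(n)
        assert r1.transform.geodesic_angle_to(truth) < 1e-6

    def test_global_rotation_of_both_maps_preserves_score(self, l_shape):
        res0 = search(l_shape, l_shape, interval=90, refine_interval=90)
        R = lattice_rotation_matrices()[5]
        rot = rotate_grid_lattice(l_shape, R)
        res1 = search(rot, rot, interval=90, refine_interval=90)
        assert res1[0].dot_score == pytest.approx(res0[0].dot_score,
                                                  rel=0.02)

    def test_cc_search_self_identity(self, l_shape):
        res = search(l_shape, l_shape, interval=90, score="cc",
                     refine_interval=90)
        r1 = res[0]
        assert r1.cc == pytest.approx(1.0, abs=1e-6)
        assert r1.transform.geodesic_angle_to(np.eye(3)) < 1e-9

    def test_lapcc_search_self_identity(self, l_shape):
        res = search(l_shape, l_shape, interval=90, score="lapcc",
                     refine_interval=90)
        assert res[0].cc == pytest.approx(1.0, abs=1e-6)
        assert res[0].transform.geodesic_angle_to(np.eye(3)) < 1e-9

    def test_results_ranked_and_bounded(self, l_shape_field):
        res = search(l_shape_field, l_shape_field, interval=90,
                     refine_interval=90)
        assert [r.rank for r in res] == list(range(1, len(res) + 1))
        for r in res:
            assert r.dot_score <= r.overlap + 1e-6
            assert r.overlap <= l_shape_field.count


class TestRigidTransform:
    def test_identity_apply(self, rng):
        p = rng.normal(size=(5, 3))
        np.testing.assert_allclose(RigidTransform.identity().apply(p), p)

    def test_inverse_composes_to_identity(self, rng):
        R = Rotation.from_euler("ZYZ", [20, 50, -30], degrees=True).as_matrix()
        t = RigidTransform(R, [3.0, -2.0, 8.0], pivot=[10.0, 5.0, -1.0])
        p = rng.normal(size=(6, 3))
        np.testing.assert_allclose(t.inverse().apply(t.apply(p)), p,
                                   atol=1e-9)

    def test_origin_form_equivalent(self, rng):
        R = Rotation.from_euler("ZYZ", [20, 50, -30], degrees=True).as_matrix()
        t = RigidTransform(R, [3.0, -2.0, 8.0], pivot=[10.0, 5.0, -1.0])
        p = rng.normal(size=(6, 3))
        np.testing.assert_allclose(t.to_origin_form().apply(p), t.apply(p),
                                   atol=1e-9)

    def test_improper_rotation_rejected(self):
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))
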