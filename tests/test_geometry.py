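"""Geometry oracles: minimum image vs 27-image brute force, dihedrals vs
an independent formula, Kabsch vs a rotation-grid search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gpianchor.geometry import (GeometryError, dihedral, kabsch_superpose,
                                make_whole, minimum_image_displacement,
                                minimum_image_distance)


def brute_force_min_image(a, b, box):
    """Minimum over the 27 periodic images of b."""
    best = None
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                d = b + np.array([i, j, k]) * box - a
                n = np.linalg.norm(d)
                if best is None or n < best:
                    best = n
    return best


def dihedral_oracle(p1, p2, p3, p4):
    """Independent dihedral formula via projections onto the plane
    normal to the central bond (not the atan2-of-normals route)."""
    b = p3 - p2
    bu = b / np.linalg.norm(b)
    v = (p1 - p2) - np.dot(p1 - p2, bu) * bu
    w = (p4 - p3) - np.dot(p4 - p3, bu) * bu
    x = np.dot(v, w)
    y = np.dot(np.cross(bu, v), w)
    return np.mod(np.degrees(np.arctan2(y, x)), 360.0)


class TestMinimumImage:
    def test_wrap_case(self):
        d = minimum_image_displacement([0.5, 0, 0], [9.5, 0, 0], [10, 10, 10])
        assert np.allclose(d, [-1.0, 0.0, 0.0])
        assert minimum_image_distance([0.5, 0, 0], [9.5, 0, 0],
                                      [10, 10, 10]) == pytest.approx(1.0)

    def test_identity(self):
        assert np.allclose(
            minimum_image_displacement([1, 2, 3], [1, 2, 3], [5, 5, 5]), 0.0)

    def test_half_box_boundary_is_positive(self):
        d = minimum_image_displacement([0, 0, 0], [2.5, -2.5, 0], [5, 5, 5])
        assert d[0] == pytest.approx(2.5)
        assert d[1] == pytest.approx(2.5)

    def test_against_27_image_brute_force(self, rng):
        box = np.array([3.0, 4.0, 5.0])
        for _ in range(1000):
            a = rng.uniform(0, 1, 3) * box
            b = rng.uniform(0, 1, 3) * box
            got = minimum_image_distance(a, b, box)
            want = brute_force_min_image(a, b, box)
            assert got == pytest.approx(want, abs=1e-12)

    def test_distance_bounded_by_half_diagonal(self, rng):
        box = np.array([2.0, 3.0, 4.0])
        pts = rng.uniform(-10, 10, size=(200, 3))
        d = minimum_image_distance(pts[:100], pts[100:], box)
        assert np.all(d <= np.linalg.norm(box / 2) + 1e-12)

    def test_antisymmetric_where_off_boundary(self, rng):
        box = np.array([5.0, 5.0, 5.0])
        a, b = rng.uniform(0, 5, 3), rng.uniform(0, 5, 3)
        assert np.allclose(minimum_image_displacement(a, b, box),
                           -minimum_image_displacement(b, a, box))


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([1, 0, 0], [0, 0, 0], [0, 1, 0],
                        [1, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        assert dihedral([-1, 0, 0], [0, 0, 0], [0, 1, 0],
                        [1, 1, 0]) == pytest.approx(180.0, abs=1e-12)

    def test_against_independent_formula(self, rng):
        for _ in range(300):
            p = rng.normal(size=(4, 3))
            try:
                got = float(dihedral(*p))
            except GeometryError:
                continue
            want = dihedral_oracle(*p)
            diff = abs((got - want + 180.0) % 360.0 - 180.0)
            assert diff < 1e-9

    def test_reversal_invariance(self, rng):
        # the signed dihedral is invariant under reversing the quadruple
        for _ in range(100):
            p = rng.normal(size=(4, 3))
            fwd = float(dihedral(p[0], p[1], p[2], p[3]))
            rev = float(dihedral(p[3], p[2], p[1], p[0]))
            assert abs((fwd - rev + 180.0) % 360.0 - 180.0) < 1e-9

    def test_periodic_quadruple_matches_unwrapped(self):
        box = np.array([2.0, 2.0, 2.0])
        p = np.array([[0.1, 0.1, 0.1], [1.95, 0.1, 0.1],
                      [1.8, 0.25, 0.1], [1.8, 0.3, 0.25]])
        unwrapped = p.copy()
        unwrapped[1:, 0] -= 2.0   # shift the wrapped atoms back
        got = float(dihedral(*p, box=box))
        want = float(dihedral(*unwrapped))
        assert abs((got - want + 180.0) % 360.0 - 180.0) < 1e-9

    def test_degenerate_raises(self):
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])
        with pytest.raises(GeometryError, match="collinear"):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0])

    def test_mdanalysis_cross_check(self, rng):
        from MDAnalysis.lib.distances import calc_dihedrals
        p = rng.normal(size=(50, 4, 3))
        want = np.mod(np.degrees(calc_dihedrals(
            p[:, 0], p[:, 1], p[:, 2], p[:, 3])), 360.0)
        got = dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
        diff = np.abs((got - want + 180.0) % 360.0 - 180.0)
        # MDAnalysis evaluates in single precision
        assert np.max(diff) < 1e-3


def random_rotation(rng):
    from scipy.spatial.transform import Rotation
    return Rotation.random(rng=np.random.RandomState(
        int(rng.integers(2 ** 31)))).as_matrix()


def grid_search_rmsd(mobile, reference, levels=5):
    """Hierarchical rotation-grid minimisation of the superposed RMSD,
    independent of the SVD solution."""
    from scipy.spatial.transform import Rotation
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def rmsd_of(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        d = mob @ R.T - ref
        return np.sqrt(np.mean(np.sum(d * d, axis=1)))

    best_vec, best = np.zeros(3), rmsd_of(np.zeros(3))
    span = np.pi
    grid = np.linspace(-1.0, 1.0, 7)
    for _ in range(levels):
        for dx in grid:
            for dy in grid:
                for dz in grid:
                    v = best_vec + span * np.array([dx, dy, dz])
                    r = rmsd_of(v)
                    if r < best:
                        best, best_vec = r, v
        span /= 3.0
    return best


class TestKabsch:
    def test_identity(self, rng):
        x = rng.normal(size=(10, 3))
        res = kabsch_superpose(x, x)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_rotation_recovered(self, rng):
        x = rng.normal(size=(20, 3))
        Rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)
        y = x @ Rz.T + np.array([1.0, -2.0, 0.5])
        res = kabsch_superpose(y, x)
        assert res.rmsd <= 1e-10
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_noisy_copy_matches_grid_search(self, rng):
        x = rng.normal(scale=0.3, size=(50, 3))
        R = random_rotation(rng)
        y = x @ R.T + rng.normal(scale=0.01, size=(50, 3))
        res = kabsch_superpose(y, x)
        want = grid_search_rmsd(y, x)
        assert res.rmsd <= want * 1.0001           # optimal beats any grid point
        assert abs(res.rmsd - want) / want < 0.05  # and the grid gets close

    def test_rmsd_invariant_under_rigid_transform_of_mobile(self, rng):
        x = rng.normal(size=(15, 3))
        y = x + rng.normal(scale=0.05, size=(15, 3))
        base = kabsch_superpose(y, x).rmsd
        R = random_rotation(rng)
        moved = y @ R.T + np.array([3.0, -1.0, 2.0])
        assert kabsch_superpose(moved, x).rmsd == pytest.approx(base, abs=1e-9)

    def test_reflection_excluded(self):
        x = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        y = x.copy()
        y[:, 2] *= -1   # mirror image
        res = kabsch_superpose(y, x)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert res.rmsd > 0.1

    def test_collinear_fit_raises(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(GeometryError, match="collinear"):
            kabsch_superpose(line, line)

    def test_measure_set_differs_from_fit(self, rng):
        x = rng.normal(size=(10, 3))
        y = x.copy()
        y[8:] += 0.5   # perturb only the measured tail
        res = kabsch_superpose(y, x, fit_indices=range(8),
                               measure_indices=[8, 9])
        assert res.rmsd == pytest.approx(np.sqrt(3 * 0.5 ** 2), abs=1e-9)


class TestMakeWhole:
    def test_chain_across_boundary(self):
        box = np.array([2.0, 2.0, 2.0])
        coords = np.array([[1.9, 0.5, 0.5], [0.05, 0.5, 0.5],
                           [0.2, 0.5, 0.5]])
        whole = make_whole(coords, box, [(0, 1), (1, 2)])
        assert np.allclose(whole[1], [2.05, 0.5, 0.5])
        assert np.allclose(whole[2], [2.2, 0.5, 0.5])

    def test_unbonded_atoms_untouched(self):
        coords = np.array([[0.1, 0.1, 0.1], [1.9, 1.9, 1.9]])
        whole = make_whole(coords, [2.0, 2.0, 2.0], [])
        assert np.allclose(whole, coords)
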