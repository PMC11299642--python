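"""Internal-coordinate metrics and structure comparison."""

import math

import numpy as np
import pytest

import radscav as rs
from radscav.datamodel import MoleculeGeometry, ValidationError
from radscav.geometry import (
    bond_angle,
    bond_length,
    compare_geometries,
    dihedral,
    hbond_geometry,
    mean_plane_rmsd,
    plane_plane_angle,
)
from conftest import rotation_about_x


def geometry_from_points(points, element="C"):
    points = np.asarray(points, dtype=float)
    labels = tuple(f"{element}{i + 1}" for i in range(len(points)))
    return MoleculeGeometry(labels, (element,) * len(points), points)


class TestInternalCoordinates:
    def test_collinear_triple_is_180(self):
        g = geometry_from_points([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        assert bond_angle(g, "C1", "C2", "C3") == pytest.approx(180.0)

    def test_square_corner_is_90(self):
        g = geometry_from_points([(0, 0, 0), (1, 0, 0), (1, 1, 0)])
        assert bond_angle(g, "C1", "C2", "C3") == pytest.approx(90.0)

    def test_dihedral_of_gauche_arrangement(self):
        g = geometry_from_points([(1, 1, 0), (1, 0, 0), (0, 0, 0), (0, 1, 1)])
        # +-45 degrees by construction (unit rise over unit offset)
        assert abs(dihedral(g, "C1", "C2", "C3", "C4")) == pytest.approx(45.0)

    def test_rigid_motion_leaves_internal_coordinates(self, hexagon, random_rotation):
        moved = hexagon.transformed(random_rotation, np.array([3.0, -2.0, 7.5]))
        assert bond_length(moved, "C1", "C2") == pytest.approx(
            bond_length(hexagon, "C1", "C2"), abs=1e-9)
        assert bond_angle(moved, "C1", "C2", "C3") == pytest.approx(
            bond_angle(hexagon, "C1", "C2", "C3"), abs=1e-9)
        assert abs(dihedral(moved, "C1", "C2", "C3", "C4")) == pytest.approx(
            abs(dihedral(hexagon, "C1", "C2", "C3", "C4")), abs=1e-9)

    def test_unknown_label_raises(self, hexagon):
        with pytest.raises(KeyError):
            bond_length(hexagon, "C1", "Zz9")

    def test_collinear_dihedral_rejected(self):
        g = geometry_from_points([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0)])
        with pytest.raises(ValidationError):
            dihedral(g, "C1", "C2", "C3", "C4")


def grid_search_plane_rmsd(points, n_coarse=360):
    """Independent oracle: scan unit normals on a spherical grid, refine."""
    points = np.asarray(points, float)
    centered = points - points.mean(axis=0)

    def rmsd_of(theta, phi):
        n = np.array([math.sin(theta) * math.cos(phi),
                      math.sin(theta) * math.sin(phi),
                      math.cos(theta)])
        d = centered @ n
        return math.sqrt(np.mean(d ** 2))

    best = (None, math.inf)
    for theta in np.linspace(0, math.pi, n_coarse):
        for phi in np.linspace(0, 2 * math.pi, n_coarse, endpoint=False):
            value = rmsd_of(theta, phi)
            if value < best[1]:
                best = ((theta, phi), value)
    from scipy.optimize import minimize

    res = minimize(lambda x: rmsd_of(*x), best[0], method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14})
    return res.fun


class TestMeanPlane:
    def test_coplanar_hexagon_is_zero(self, hexagon):
        assert mean_plane_rmsd(hexagon, hexagon.labels) == pytest.approx(0.0, abs=1e-12)

    def test_displaced_atom_matches_grid_search_oracle(self, hexagon):
        coords = hexagon.coords.copy()
        coords[0, 2] += 0.1
        g = MoleculeGeometry(hexagon.labels, hexagon.elements, coords)
        rmsd = mean_plane_rmsd(g, g.labels)
        assert rmsd == pytest.approx(grid_search_plane_rmsd(coords, n_coarse=90),
                                     abs=1e-6)

    def test_matches_eigendecomposition_oracle_on_random_sets(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            points = rng.normal(size=(8, 3))
            g = geometry_from_points(points)
            centered = points - points.mean(axis=0)
            evals = np.linalg.eigh(centered.T @ centered)[0]
            oracle = math.sqrt(max(evals[0], 0.0) / len(points))
            assert mean_plane_rmsd(g, g.labels) == pytest.approx(oracle, abs=1e-9)

    def test_rotation_invariance(self, hexagon, random_rotation):
        coords = hexagon.coords.copy()
        coords[2, 2] -= 0.07
        g = MoleculeGeometry(hexagon.labels, hexagon.elements, coords)
        moved = g.transformed(random_rotation, np.array([1.0, 2.0, 3.0]))
        assert mean_plane_rmsd(moved, g.labels) == pytest.approx(
            mean_plane_rmsd(g, g.labels), abs=1e-9)

    def test_collinear_set_rejected(self):
        g = geometry_from_points([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        with pytest.raises(ValidationError):
            mean_plane_rmsd(g, g.labels)


class TestPlanePlaneAngle:
    def build_two_rings(self, angle_deg):
        from radscav.simulate import regular_polygon_geometry

        ring = regular_polygon_geometry(6, 1.4)
        rotated = ring.coords @ rotation_about_x(angle_deg).T + np.array([5.0, 0, 0])
        labels = ring.labels + tuple(f"D{i + 1}" for i in range(6))
        elements = ring.elements * 2
        coords = np.vstack([ring.coords, rotated])
        return MoleculeGeometry(labels, elements, coords), ring.labels, \
            tuple(f"D{i + 1}" for i in range(6))

    def test_parallel_rings(self):
        g, l1, l2 = self.build_two_rings(0.0)
        assert plane_plane_angle(g, l1, l2) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_rings(self):
        g, l1, l2 = self.build_two_rings(90.0)
        assert plane_plane_angle(g, l1, l2) == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("angle", [57.83, 63.63, 18.13, 120.0])
    def test_constructed_angle_recovered_acutely(self, angle):
        g, l1, l2 = self.build_two_rings(angle)
        expected = angle if angle <= 90.0 else 180.0 - angle
        assert plane_plane_angle(g, l1, l2) == pytest.approx(expected, abs=1e-6)


class TestHBond:
    def test_collinear_hydrogen(self):
        g = MoleculeGeometry(("D", "H", "A"), ("C", "H", "O"),
                             np.array([[0, 0, 0], [1, 0, 0], [3, 0, 0]], float))
        hb = hbond_geometry(g, "D", "H", "A")
        assert hb.angle_dha == pytest.approx(180.0)
        assert hb.d_da == pytest.approx(hb.d_dh + hb.d_ha)

    def test_law_of_cosines_construction(self):
        # place D-H = 0.93 A, H...A = 2.35 A with a 150 degree D-H...A angle;
        # the donor-acceptor distance then follows from the law of cosines
        d_dh, d_ha, theta = 0.93, 2.35, math.radians(150.0)
        acceptor = np.array([d_dh + d_ha * math.cos(math.pi - theta),
                             d_ha * math.sin(math.pi - theta), 0.0])
        g = MoleculeGeometry(("D", "H", "A"), ("C", "H", "O"),
                             np.array([[0, 0, 0], [d_dh, 0, 0], acceptor]))
        hb = hbond_geometry(g, "D", "H", "A")
        assert hb.angle_dha == pytest.approx(150.0, abs=0.5)
        expected_da = math.sqrt(d_dh ** 2 + d_ha ** 2
                                - 2 * d_dh * d_ha * math.cos(theta))
        assert hb.d_da == pytest.approx(expected_da, abs=1e-9)
        assert hb.d_da == pytest.approx(3.1894, abs=1e-3)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            g = MoleculeGeometry(("D", "H", "A"), ("C", "H", "O"),
                                 rng.normal(size=(3, 3)))
            hb = hbond_geometry(g, "D", "H", "A")
            assert hb.d_da <= hb.d_dh + hb.d_ha + 1e-12


class TestCompareGeometries:
    def test_identical_structures_have_zero_deviation(self, hexagon):
        bonds = [("C1", "C2"), ("C2", "C3")]
        angles = [("C1", "C2", "C3")]
        result = compare_geometries(hexagon, hexagon, bonds, angles)
        assert result.max_bond_dev == 0.0
        assert result.max_angle_dev == 0.0

    def test_single_stretched_bond(self, hexagon):
        coords = hexagon.coords.copy()
        direction = coords[1] - coords[0]
        coords[1] += 0.02 * direction / np.linalg.norm(direction)
        stretched = MoleculeGeometry(hexagon.labels, hexagon.elements, coords)
        result = compare_geometries(hexagon, stretched, [("C1", "C2")])
        assert result.max_bond_dev == pytest.approx(0.02, abs=1e-9)

    def test_invariant_under_independent_rigid_motions(self, hexagon, random_rotation):
        bonds = [("C1", "C2"), ("C3", "C4")]
        angles = [("C2", "C3", "C4")]
        moved = hexagon.transformed(random_rotation, np.array([-4.0, 1.0, 9.0]))
        a = compare_geometries(hexagon, hexagon, bonds, angles)
        b = compare_geometries(hexagon, moved, bonds, angles)
        assert b.max_bond_dev == pytest.approx(a.max_bond_dev, abs=1e-9)
        assert b.max_angle_dev == pytest.approx(a.max_angle_dev, abs=1e-9)

    def test_label_mapping_applied_and_checked(self, hexagon):
        relabeled = MoleculeGeometry(
            tuple(f"X{i}" for i in range(6)), hexagon.elements, hexagon.coords)
        mapping = {f"C{i + 1}": f"X{i}" for i in range(6)}
        result = compare_geometries(hexagon, relabeled, [("C1", "C2")], mapping=mapping)
        assert result.max_bond_dev == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValidationError, match="missing"):
            compare_geometries(hexagon, relabeled, [("C1", "C2")], mapping={})
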