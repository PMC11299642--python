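"""Internal-coordinate geometry metrics and structure comparison.

Everything here is a function of interatomic geometry only: bond lengths,
angles, dihedrals, least-squares mean planes, inter-plane angles, hydrogen
bond geometry, and reference-vs-test comparison of internal coordinates
(no superposition is performed, so results are rigid-motion invariant by
construction).  Typical use is comparing a DFT-optimized structure against
an experimental crystal structure exported to XYZ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np

from .datamodel import MoleculeGeometry, ValidationError

__all__ = [
    "GeometryComparison",
    "HBondGeometry",
    "bond_length",
    "bond_angle",
    "dihedral",
    "mean_plane_rmsd",
    "plane_plane_angle",
    "hbond_geometry",
    "compare_geometries",
]

_DEGENERATE = 1e-10


def bond_length(g: MoleculeGeometry, a: str, b: str) -> float:
    """Euclidean distance between two labeled atoms, in angstrom."""
    return float(np.linalg.norm(g.position(a) - g.position(b)))


def bond_angle(g: MoleculeGeometry, a: str, b: str, c: str) -> float:
    """Angle a-b-c at vertex b, in degrees."""
    u = g.position(a) - g.position(b)
    v = g.position(c) - g.position(b)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < _DEGENERATE or nv < _DEGENERATE:
        raise ValidationError("coincident atoms: angle undefined")
    cosine = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return math.degrees(math.acos(cosine))


def dihedral(g: MoleculeGeometry, a: str, b: str, c: str, d: str) -> float:
    """Signed torsion a-b-c-d in degrees, in (-180, 180]."""
    p = [g.position(x) for x in (a, b, c, d)]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGENERATE or np.linalg.norm(n2) < _DEGENERATE:
        raise ValidationError("collinear atoms: dihedral undefined")
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = math.degrees(math.atan2(np.dot(m1, n2), np.dot(n1, n2)))
    return angle


def _best_fit_normal(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane of a point set: (unit normal, singular values).

    The plane passes through the centroid; its normal is the right singular
    vector of the centered coordinates with the smallest singular value.
    """
    centered = points - points.mean(axis=0)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1], svals


def mean_plane_rmsd(g: MoleculeGeometry, labels: Sequence[str]) -> float:
    """R.m.s. perpendicular deviation (angstrom) from the best-fit plane.

    Zero iff the atoms are exactly coplanar; requires >= 3 non-collinear atoms.
    """
    points = g.subset(labels)
    if len(points) < 3:
        raise ValidationError("mean plane needs at least 3 atoms")
    normal, svals = _best_fit_normal(points)
    if svals[1] < _DEGENERATE:
        raise ValidationError("collinear atom set: plane undefined")
    distances = (points - points.mean(axis=0)) @ normal
    return float(np.sqrt(np.mean(distances ** 2)))


def plane_plane_angle(g: MoleculeGeometry, labels_1: Sequence[str],
                      labels_2: Sequence[str]) -> float:
    """Acute angle (degrees, in [0, 90]) between two best-fit planes."""
    angle_cos = []
    normals = []
    for labels in (labels_1, labels_2):
        points = g.subset(labels)
        if len(points) < 3:
            raise ValidationError("plane needs at least 3 atoms")
        normal, svals = _best_fit_normal(points)
        if svals[1] < _DEGENERATE:
            raise ValidationError("collinear atom set: plane undefined")
        normals.append(normal)
    cosine = abs(float(np.dot(normals[0], normals[1])))
    return math.degrees(math.acos(np.clip(cosine, 0.0, 1.0)))


class HBondGeometry(NamedTuple):
    d_dh: float  # donor-H, angstrom
    d_ha: float  # H...acceptor, angstrom
    d_da: float  # donor...acceptor, angstrom
    angle_dha: float  # D-H...A, degrees


def hbond_geometry(g: MoleculeGeometry, donor: str, h: str, acceptor: str) -> HBondGeometry:
    """The three distances and the D-H...A angle of a hydrogen bond."""
    return HBondGeometry(
        d_dh=bond_length(g, donor, h),
        d_ha=bond_length(g, h, acceptor),
        d_da=bond_length(g, donor, acceptor),
        angle_dha=bond_angle(g, donor, h, acceptor),
    )


@dataclass(frozen=True)
class GeometryComparison:
    """Per-internal-coordinate deviations between reference and test structures.

    Percent deviations use the reference (e.g. crystal) value as denominator.
    """

    bond_deviations: tuple[tuple[tuple[str, str], float, float], ...]
    angle_deviations: tuple[tuple[tuple[str, str, str], float, float], ...]
    max_bond_dev: float
    max_angle_dev: float

    def __post_init__(self) -> None:
        if self.bond_deviations:
            if not math.isclose(self.max_bond_dev,
                                max(d for _, d, _ in self.bond_deviations)):
                raise ValidationError("max_bond_dev inconsistent with its list")
        if self.angle_deviations:
            if not math.isclose(self.max_angle_dev,
                                max(d for _, d, _ in self.angle_deviations)):
                raise ValidationError("max_angle_dev inconsistent with its list")


def compare_geometries(g_ref: MoleculeGeometry, g_test: MoleculeGeometry,
                       bonds: Sequence[tuple[str, str]],
                       angles: Sequence[tuple[str, str, str]] = (),
                       mapping: Optional[Mapping[str, str]] = None) -> GeometryComparison:
    """Absolute and percent deviations of selected bonds/angles.

    ``mapping`` translates reference labels to test labels (identity by
    default); all labels referenced by ``bonds``/``angles`` must be covered.
    """
    def mapped(label: str) -> str:
        if mapping is None:
            return label
        try:
            return mapping[label]
        except KeyError:
            raise ValidationError(f"atom {label!r} missing from the label mapping") from None

    bond_rows = []
    for a, b in bonds:
        ref = bond_length(g_ref, a, b)
        test = bond_length(g_test, mapped(a), mapped(b))
        dev = abs(test - ref)
        bond_rows.append(((a, b), dev, 100.0 * dev / ref))
    angle_rows = []
    for a, b, c in angles:
        ref = bond_angle(g_ref, a, b, c)
        test = bond_angle(g_test, mapped(a), mapped(b), mapped(c))
        dev = abs(test - ref)
        angle_rows.append(((a, b, c), dev, 100.0 * dev / ref))
    return GeometryComparison(
        bond_deviations=tuple(bond_rows),
        angle_deviations=tuple(angle_rows),
        max_bond_dev=max((d for _, d, _ in bond_rows), default=0.0),
        max_angle_dev=max((d for _, d, _ in angle_rows), default=0.0),
    )
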