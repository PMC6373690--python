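"""Core 3D primitives.

Distances, the all-pairs polygon error metric, bond angles and torsions,
internal-to-Cartesian chain building (NeRF-style placement), and rigid
Kabsch superposition restricted to proper rotations.

Units are Å for lengths and radians for angles throughout the library;
degree input is converted at the CLI/config boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .errors import DegenerateGeometryError, ParameterError, SizeMismatchError

__all__ = [
    "TargetPolygon",
    "CandidateConfiguration",
    "RigidTransform",
    "ChainSpec",
    "as_points",
    "polygon_error",
    "bond_angle",
    "dihedral_angle",
    "place_atom",
    "internal_to_cartesian",
    "measure_internal",
    "superpose",
]

_EPS = 1e-12


def as_points(x) -> np.ndarray:
    """Coerce to an (n, 3) float array of finite 3D points."""
    pts = np.atleast_2d(np.asarray(x, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise SizeMismatchError(f"expected an (n, 3) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ParameterError("points must have finite components")
    return pts


@dataclass(frozen=True)
class TargetPolygon:
    """An ordered list of n >= 2 vertices with the full pairwise distance table.

    The "polygon" is really a spatial pattern: the search constrains all
    n(n-1)/2 pairwise distances, not only the perimeter edges.
    """

    vertices: np.ndarray
    edge_lengths: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        verts = as_points(self.vertices)
        if len(verts) < 2:
            raise SizeMismatchError("a target polygon needs at least 2 vertices")
        object.__setattr__(self, "vertices", verts)
        diff = verts[:, None, :] - verts[None, :, :]
        object.__setattr__(self, "edge_lengths", np.linalg.norm(diff, axis=-1))

    @property
    def n(self) -> int:
        return len(self.vertices)

    def edge_length(self, i: int, j: int) -> float:
        return float(self.edge_lengths[i, j])

    @property
    def diameter(self) -> float:
        return float(self.edge_lengths.max())


@dataclass(frozen=True)
class CandidateConfiguration:
    """A candidate n-point configuration with its realized error vs a target."""

    points: np.ndarray
    error: float

    @classmethod
    def from_points(cls, points, target: TargetPolygon) -> "CandidateConfiguration":
        pts = as_points(points)
        return cls(points=pts, error=polygon_error(pts, target))


def polygon_error(candidate, target) -> float:
    """Maximum pairwise-distance deviation between two equally sized point sets.

    For target P and candidate S of n points each this is
    ``max over i < j of | |PiPj| - |SiSj| |`` -- the error metric the whole
    search is built around.  It is invariant under rigid motions *and*
    reflections of either set, which is why chirality must be resolved
    downstream by enantiomer enumeration.
    """
    s = candidate.points if isinstance(candidate, CandidateConfiguration) else as_points(candidate)
    p = target.vertices if isinstance(target, TargetPolygon) else as_points(target)
    if len(s) != len(p):
        raise SizeMismatchError(f"vertex counts differ: candidate {len(s)} vs target {len(p)}")
    if len(s) < 2:
        raise SizeMismatchError("need at least 2 vertices to compare distances")
    return float(np.abs(pdist(p) - pdist(s)).max())


def bond_angle(a, b, c) -> float:
    """Angle at vertex ``b`` of the triple a-b-c, in [0, pi]."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    u = a - b
    w = c - b
    nu = np.linalg.norm(u)
    nw = np.linalg.norm(w)
    if nu < _EPS or nw < _EPS:
        raise DegenerateGeometryError("bond angle undefined: zero-length arm")
    cosang = np.clip(np.dot(u, w) / (nu * nw), -1.0, 1.0)
    return float(np.arccos(cosang))


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion of the four points about the p1-p2 axis, in (-pi, pi]."""
    p0, p1, p2, p3 = (np.asarray(x, dtype=float) for x in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    nb1 = np.linalg.norm(b1)
    if nb1 < _EPS:
        raise DegenerateGeometryError("torsion undefined: zero-length axis")
    b1 = b1 / nb1
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < _EPS or np.linalg.norm(w) < _EPS:
        raise DegenerateGeometryError("torsion undefined: collinear frame")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.arctan2(y, x))


def place_atom(a, b, c, length: float, angle: float, dihedral: float) -> np.ndarray:
    """Place a new atom D from the frame (a, b, c).

    D is at distance ``length`` from ``c``, makes bond angle ``angle`` at
    ``c`` with the b-c bond, and torsion ``dihedral`` about the b-c axis
    measured against a.  Standard natural-extension (NeRF) placement.
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    if length <= 0:
        raise ParameterError("bond length must be positive")
    bc = c - b
    nbc = np.linalg.norm(bc)
    ab = b - a
    if nbc < _EPS or np.linalg.norm(ab) < _EPS:
        raise DegenerateGeometryError("degenerate placement frame")
    bc = bc / nbc
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _EPS:
        raise DegenerateGeometryError("collinear placement frame")
    n = n / nn
    m = np.cross(n, bc)
    # local displacement in the (bc, m, n) frame
    d_local = np.array(
        [
            -length * np.cos(angle),
            length * np.sin(angle) * np.cos(dihedral),
            length * np.sin(angle) * np.sin(dihedral),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x -> R x + t (det R = +1, no reflections)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ParameterError("rotation matrix is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ParameterError("reflections are not allowed in a RigidTransform")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points) -> np.ndarray:
        pts = as_points(points)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass(frozen=True)
class ChainSpec:
    """Internal-coordinate description of a linear side chain.

    The chain extends atom by atom from a three-point anchor frame.  Atom k
    is placed with bond length ``bond_lengths[k]`` from atom k-1, bond angle
    ``bond_angles[k]`` at atom k-1, and a torsion about the incoming bond.
    Torsions flagged ``rotatable`` are supplied at build time; the rest are
    frozen at ``fixed_dihedrals`` (default trans, pi).
    """

    atom_names: tuple
    bond_lengths: np.ndarray
    bond_angles: np.ndarray
    rotatable: np.ndarray
    fixed_dihedrals: np.ndarray = None

    def __post_init__(self):
        names = tuple(self.atom_names)
        m = len(names)
        lengths = np.asarray(self.bond_lengths, dtype=float).reshape(m)
        angles = np.asarray(self.bond_angles, dtype=float).reshape(m)
        rot = np.asarray(self.rotatable, dtype=bool).reshape(m)
        fixed = self.fixed_dihedrals
        fixed = np.full(m, np.pi) if fixed is None else np.asarray(fixed, dtype=float).reshape(m)
        if np.any(lengths <= 0):
            raise ParameterError("bond lengths must be positive")
        if np.any(angles <= 0) or np.any(angles >= np.pi):
            raise ParameterError("bond angles must lie strictly inside (0, pi)")
        object.__setattr__(self, "atom_names", names)
        object.__setattr__(self, "bond_lengths", lengths)
        object.__setattr__(self, "bond_angles", angles)
        object.__setattr__(self, "rotatable", rot)
        object.__setattr__(self, "fixed_dihedrals", fixed)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def n_rotatable(self) -> int:
        return int(self.rotatable.sum())


def internal_to_cartesian(spec: ChainSpec, dihedrals, anchor) -> np.ndarray:
    """Instantiate a chain spec at the given rotatable-bond torsions.

    ``anchor`` is a (3, 3) array of seed points; the first chain atom is
    placed off ``anchor[2]``.  Returns the (n_atoms, 3) coordinates of the
    chain atoms only.  Placement is exact: remeasuring bond lengths and
    angles from the output reproduces the spec to ~1e-12.
    """
    anchor = as_points(anchor)
    if anchor.shape != (3, 3):
        raise SizeMismatchError("anchor must consist of exactly three seed points")
    # degenerate frame check
    if np.linalg.norm(np.cross(anchor[1] - anchor[0], anchor[2] - anchor[1])) < 1e-9:
        raise DegenerateGeometryError("anchor points are collinear")
    dihedrals = np.asarray(dihedrals, dtype=float).reshape(-1)
    if len(dihedrals) != spec.n_rotatable:
        raise SizeMismatchError(
            f"expected {spec.n_rotatable} dihedrals for the rotatable bonds, got {len(dihedrals)}"
        )
    torsions = spec.fixed_dihedrals.copy()
    torsions[spec.rotatable] = dihedrals
    frame = [anchor[0], anchor[1], anchor[2]]
    out = np.empty((spec.n_atoms, 3))
    for k in range(spec.n_atoms):
        atom = place_atom(
            frame[-3], frame[-2], frame[-1],
            spec.bond_lengths[k], spec.bond_angles[k], torsions[k],
        )
        out[k] = atom
        frame.append(atom)
    return out


def measure_internal(anchor, atoms):
    """Recover (bond_lengths, bond_angles, torsions) of a chain built off ``anchor``.

    The inverse of :func:`internal_to_cartesian`; used for round-trip checks.
    """
    anchor = as_points(anchor)
    atoms = as_points(atoms)
    chain = np.vstack([anchor, atoms])
    m = len(atoms)
    lengths = np.empty(m)
    angles = np.empty(m)
    torsions = np.empty(m)
    for k in range(m):
        i = 3 + k  # index of atom k in the padded chain
        lengths[k] = np.linalg.norm(chain[i] - chain[i - 1])
        angles[k] = bond_angle(chain[i - 2], chain[i - 1], chain[i])
        torsions[k] = dihedral_angle(chain[i - 3], chain[i - 2], chain[i - 1], chain[i])
    return lengths, angles, torsions


def superpose(mobile, fixed):
    """Least-squares rigid superposition of ``mobile`` onto ``fixed``.

    Kabsch algorithm restricted to proper rotations (the transform is
    applied to physical scaffolds, so mirror solutions are excluded even
    when they would score better).  Returns ``(RigidTransform, rmsd)``
    where applying the transform to ``mobile`` realizes the RMSD.
    """
    mob = as_points(mobile)
    fix = as_points(fixed)
    if len(mob) != len(fix):
        raise SizeMismatchError("superpose needs equally many mobile and fixed points")
    if len(mob) < 3:
        raise DegenerateGeometryError("superpose needs at least 3 points")
    cm = mob.mean(axis=0)
    cf = fix.mean(axis=0)
    a = mob - cm
    b = fix - cf
    # collinear sets leave a free rotation about the common axis: ill-posed
    for centered, tag in ((a, "mobile"), (b, "fixed")):
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise DegenerateGeometryError(f"{tag} points are collinear; superposition is ill-posed")
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cf - rot @ cm
    transform = RigidTransform(rot, trans)
    moved = transform.apply(mob)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - fix) ** 2, axis=1))))
    return transform, rmsd
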