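"""Scaffold screening against hotspot-residue stubs.

The screen enumerates, for every scaffold, all n-subsets of its take-off
sites and all 2^n d/l enantiomer assignments of the involved residues,
compares the resulting take-off polygon against the stub polygon, places
the survivors by rigid superposition, and keeps those whose junction bond
angles stay within tolerance of the stub's optimal values.  Survivors are
scored by a shape RMSD (superposition residual) and an angle RMSD
(junction-angle deviations).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, InsufficientSitesError, SizeMismatchError
from .geometry import TargetPolygon, bond_angle, polygon_error, superpose
from .manifold import Manifold
from .octree import build_octree, common_root_side
from .pair_search import ToleranceModel, adaptive_pair_search
from . import assembly

log = logging.getLogger(__name__)

__all__ = [
    "ScaffoldResidue",
    "ScaffoldGeometry",
    "HotspotStub",
    "JunctionAngle",
    "ScaffoldMatch",
    "mirror_residue",
    "mirror_scaffold",
    "enumerate_targets",
    "match_scaffold",
    "rank_matches",
]


@dataclass(frozen=True)
class ScaffoldResidue:
    """One residue of a scaffold: named atoms plus its backbone frame atoms.

    The three backbone atoms define the local plane used to flip the
    residue between its d and l enantiomers.
    """

    name: str
    atoms: dict  # atom name -> (3,) coordinates
    backbone: tuple = ("N", "CA", "C")

    def __post_init__(self):
        coords = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.atoms.items()}
        object.__setattr__(self, "atoms", coords)
        for b in self.backbone:
            if b not in coords:
                raise SizeMismatchError(f"residue {self.name} lacks backbone atom {b}")


@dataclass(frozen=True)
class ScaffoldGeometry:
    """A scaffold: residues, candidate take-off sites, enantiomer tags."""

    scaffold_id: str
    residues: tuple
    takeoff_sites: tuple  # ((residue_index, atom_name), ...)
    enantiomer_labels: tuple = None

    def __post_init__(self):
        object.__setattr__(self, "residues", tuple(self.residues))
        object.__setattr__(self, "takeoff_sites", tuple(tuple(s) for s in self.takeoff_sites))
        labels = self.enantiomer_labels
        if labels is None:
            labels = tuple("L" for _ in self.residues)
        object.__setattr__(self, "enantiomer_labels", tuple(labels))
        for ri, aname in self.takeoff_sites:
            if not (0 <= ri < len(self.residues)) or aname not in self.residues[ri].atoms:
                raise SizeMismatchError(f"take-off site ({ri}, {aname}) not present in scaffold")

    @property
    def n_sites(self) -> int:
        return len(self.takeoff_sites)

    def site_coord(self, site_idx: int, mirrored: bool = False) -> np.ndarray:
        ri, aname = self.takeoff_sites[site_idx]
        res = self.residues[ri]
        if mirrored:
            res = mirror_residue(res)
        return res.atoms[aname]

    def all_atom_coords(self) -> np.ndarray:
        return np.vstack([
            res.atoms[a] for res in self.residues for a in sorted(res.atoms)
        ])


def _reflect_through_plane(point, origin, normal):
    v = point - origin
    return point - 2.0 * np.dot(v, normal) * normal


def mirror_residue(res: ScaffoldResidue) -> ScaffoldResidue:
    """Reflect the residue's side atoms through its backbone plane (d <-> l)."""
    a, b, c = (res.atoms[k] for k in res.backbone)
    n = np.cross(b - a, c - b)
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        raise DegenerateGeometryError(
            f"residue {res.name}: backbone atoms are collinear, mirror plane undefined"
        )
    n = n / nn
    new_atoms = {}
    for name, xyz in res.atoms.items():
        if name in res.backbone:
            new_atoms[name] = xyz
        else:
            new_atoms[name] = _reflect_through_plane(xyz, b, n)
    return ScaffoldResidue(name=res.name, atoms=new_atoms, backbone=res.backbone)


def mirror_scaffold(s: ScaffoldGeometry, residue_indices) -> ScaffoldGeometry:
    """Flip the enantiomer of the named residues; applying twice restores the input."""
    idx = set(residue_indices)
    flipped = {"L": "D", "D": "L"}
    residues = tuple(
        mirror_residue(r) if i in idx else r for i, r in enumerate(s.residues)
    )
    labels = tuple(
        flipped.get(lab, lab) if i in idx else lab
        for i, lab in enumerate(s.enantiomer_labels)
    )
    return ScaffoldGeometry(
        scaffold_id=s.scaffold_id,
        residues=residues,
        takeoff_sites=s.takeoff_sites,
        enantiomer_labels=labels,
    )


@dataclass(frozen=True)
class SiteAssignment:
    """One search instance: a site combination plus an enantiomer mask."""

    sites: tuple      # indices into takeoff_sites, ascending
    mirror_mask: tuple  # per chosen site: True = use the d-flipped residue


def enumerate_targets(s: ScaffoldGeometry, n: int):
    """All C(m, n) site combinations x 2^n enantiomer assignments.

    Yields ``(TargetPolygon, SiteAssignment)`` in deterministic
    lexicographic order; each polygon's vertices are the (possibly
    mirrored) take-off atom coordinates.
    """
    m = s.n_sites
    if m < n:
        raise InsufficientSitesError(
            f"scaffold {s.scaffold_id} has {m} take-off sites, pattern needs {n}"
        )
    out = []
    for combo in itertools.combinations(range(m), n):
        for mask in itertools.product((False, True), repeat=n):
            verts = np.array([
                s.site_coord(site, mirrored=mir) for site, mir in zip(combo, mask)
            ])
            out.append((TargetPolygon(verts), SiteAssignment(combo, mask)))
    return out


@dataclass(frozen=True)
class JunctionAngle:
    """A junction bond-angle requirement at a matched take-off site.

    The angle is measured at scaffold atom ``vertex_atom`` between scaffold
    atom ``arm_atom`` and the stub's connect-atom position (e.g. the
    N-CA-CB angle when a side chain is grafted onto the scaffold's CA).
    """

    arm_atom: str
    vertex_atom: str
    optimal: float  # radians

    def __post_init__(self):
        if not (0.0 < self.optimal < np.pi):
            raise SizeMismatchError("optimal junction angle must lie in (0, pi)")


@dataclass(frozen=True)
class HotspotStub:
    """One hotspot residue: its atoms, attachment node and junction-angle spec.

    When the hotspot side chain has rotatable bonds beyond the two fixed chi
    angles, ``manifold`` carries the cloud of possible connect-atom
    positions and the match routes through the adaptive octree search
    instead of the single fixed point.
    """

    name: str
    atoms: dict
    connect_atom: str
    optimal_angles: tuple = ()
    manifold: Manifold = None

    def __post_init__(self):
        coords = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.atoms.items()}
        object.__setattr__(self, "atoms", coords)
        if self.connect_atom not in coords:
            raise SizeMismatchError(f"stub {self.name} lacks connect atom {self.connect_atom}")
        object.__setattr__(self, "optimal_angles", tuple(self.optimal_angles))

    @property
    def connect_coord(self) -> np.ndarray:
        return self.atoms[self.connect_atom]


@dataclass(frozen=True)
class ScaffoldMatch:
    """A surviving scaffold placement with its dual RMSD scores."""

    scaffold_id: str
    sites: tuple
    order: tuple          # permutation: order[k] = site serving stub k
    mirror_mask: tuple
    transform: RigidTransform
    shape_rmsd: float
    angle_rmsd: float
    polygon_err: float

    def score(self, weight: float = 1.0) -> float:
        return self.shape_rmsd ** 2 + weight * self.angle_rmsd ** 2


def _check_angles(scaffold: ScaffoldGeometry, assignment, order, transform, stubs, delta_angle):
    """Junction-angle deviations of the placed scaffold, or None on failure."""
    devs = []
    for stub_idx, k in enumerate(order):
        site = assignment.sites[k]
        mirrored = assignment.mirror_mask[k]
        ri, _ = scaffold.takeoff_sites[site]
        res = scaffold.residues[ri]
        if mirrored:
            res = mirror_residue(res)
        stub = stubs[stub_idx]
        for ja in stub.optimal_angles:
            if ja.arm_atom not in res.atoms or ja.vertex_atom not in res.atoms:
                continue
            arm = transform.apply(res.atoms[ja.arm_atom])[0]
            vertex = transform.apply(res.atoms[ja.vertex_atom])[0]
            ang = bond_angle(arm, vertex, stub.connect_coord)
            dev = abs(ang - ja.optimal)
            if dev > delta_angle:
                return None
            devs.append(dev)
    return devs


def _stub_polygon(stubs) -> TargetPolygon:
    return TargetPolygon(np.array([st.connect_coord for st in stubs]))


def _flexible_connect_points(stubs, instance_polygon, tol):
    """Resolve flexible stubs through the octree search; None when no match.

    Builds one octree per stub manifold (fixed stubs contribute single-point
    clouds), searches every edge of the scaffold take-off polygon, and
    assembles the per-edge matches into a configuration.  Returns the
    representative connect-atom points of the first configuration found.
    """
    clouds = [
        st.manifold if st.manifold is not None else Manifold(st.connect_coord[None, :])
        for st in stubs
    ]
    centers = np.array([c.points.mean(axis=0) for c in clouds])
    l0 = max(common_root_side(clouds, tol.ls), 2 * tol.ls)
    trees = [build_octree(c, l0, tol.ls, origin=ctr) for c, ctr in zip(clouds, centers)]
    n = len(stubs)
    edge_sets = {}
    for i in range(n):
        for j in range(i + 1, n):
            target_len = instance_polygon.edge_length(i, j)
            edge_sets[(i, j)] = adaptive_pair_search(
                trees[i], trees[j], target_len, tol, edge=(i, j)
            )
    configs = assembly.assemble(edge_sets, instance_polygon, tol, limit=1)
    if not configs:
        return None
    return configs[0].points


def match_scaffold(
    scaffolds,
    stubs,
    tol: ToleranceModel = None,
    delta: float = None,
    delta_angle: float = 0.2,
) -> list:
    """Screen a scaffold library against hotspot stubs (two-step filter).

    Step 1 keeps every (site combination, enantiomer assignment, vertex
    correspondence) whose take-off polygon deviates from the stub polygon
    by at most ``delta`` in the all-pairs distance metric.  Step 2 computes
    the rigid placement of the scaffold onto the stub attachment nodes and
    keeps the match only if every junction bond angle is within
    ``delta_angle`` of its optimal value.  Per search instance the best
    correspondence is reported, with both RMSD scores.

    ``delta`` defaults to the tolerance model's eps_T; when any stub
    declares a manifold of connect positions the polygon comparison routes
    through the adaptive octree search automatically.
    """
    if isinstance(scaffolds, ScaffoldGeometry):
        scaffolds = [scaffolds]
    stubs = list(stubs)
    n = len(stubs)
    if tol is None and delta is None:
        raise SizeMismatchError("provide a ToleranceModel or an explicit delta")
    if delta is None:
        delta = tol.eps_T
    if tol is None:
        tol = ToleranceModel(eps_T=delta)
    flexible = any(st.manifold is not None for st in stubs)
    fixed_polygon = None if flexible else _stub_polygon(stubs)

    matches = []
    for scaffold in scaffolds:
        for polygon, assignment in enumerate_targets(scaffold, n):
            best = None
            for order in itertools.permutations(range(n)):
                ordered = polygon.vertices[list(order)]
                if flexible:
                    connect_pts = _flexible_connect_points(
                        stubs, TargetPolygon(ordered), tol
                    )
                    if connect_pts is None:
                        continue
                    err = polygon_error(ordered, connect_pts)
                else:
                    connect_pts = fixed_polygon.vertices
                    err = polygon_error(ordered, connect_pts)
                if err > delta:
                    continue
                try:
                    transform, shape_rmsd = superpose(ordered, connect_pts)
                except DegenerateGeometryError:
                    log.warning(
                        "skipping degenerate take-off polygon on scaffold %s sites %s",
                        scaffold.scaffold_id, assignment.sites,
                    )
                    continue
                devs = _check_angles(
                    scaffold, assignment, order, transform, stubs, delta_angle
                )
                if devs is None:
                    continue
                angle_rmsd = float(np.sqrt(np.mean(np.square(devs)))) if devs else 0.0
                cand = ScaffoldMatch(
                    scaffold_id=scaffold.scaffold_id,
                    sites=assignment.sites,
                    order=order,
                    mirror_mask=assignment.mirror_mask,
                    transform=transform,
                    shape_rmsd=shape_rmsd,
                    angle_rmsd=angle_rmsd,
                    polygon_err=err,
                )
                if best is None or cand.score() < best.score():
                    best = cand
            if best is not None:
                matches.append(best)
    return matches


def rank_matches(matches, weight: float = 1.0) -> list:
    """Sort by shape_rmsd^2 + weight * angle_rmsd^2 (weight in Å²/rad²).

    Ties break by scaffold id, then site tuple, for a reproducible ranking.
    """
    return sorted(
        matches,
        key=lambda m: (m.score(weight), m.scaffold_id, m.sites, m.mirror_mask),
    )
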