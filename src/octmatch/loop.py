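"""Bidirectional discretized loop closure.

A loop of k residues is grown as two semi-loops from its pivot anchors,
one from each end, using a precomputed table of single-residue
conformations.  Chain ends are discretized onto a cube lattice and a
direction-bin grid, states falling into the same (cube, bin) are collapsed
with predecessor links retained, and the two growths are matched in the
middle: same cube, junction bond angle within tolerance.  Matched states
are backtracked to the pivots and re-instantiated exactly in Cartesian
space; only loops that survive an exact final re-measurement are emitted.

The residue model is a three-atom N-Cα-C abstraction with uniform ideal
bond length and bond angle, and consecutive residues share the junction
atom.  Uniform geometry makes a chain read backwards obey the same
internal-coordinate model as one read forwards, which is what lets a
product dihedral grid represent both semi-loops of the same closed loop.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, OutOfBoundsError, ParameterError
from .geometry import bond_angle, place_atom

__all__ = [
    "BOND_LENGTH",
    "BOND_ANGLE",
    "LatticeSpec",
    "LoopSpec",
    "ResidueConformation",
    "SemiLoopState",
    "LoopResult",
    "canonical_anchor",
    "precompute_conformations",
    "build_connectivity",
    "residues_connect",
    "grow_semiloop",
    "match_and_backtrack",
    "instantiate_chain",
]

BOND_LENGTH = 1.5          # Å, uniform across the N-Cα-C abstraction
BOND_ANGLE = np.deg2rad(111.0)  # uniform ideal bond angle


# ---------------------------------------------------------------------------
# lattice and direction binning

@dataclass(frozen=True)
class LatticeSpec:
    """Axis-aligned cube lattice covering the designated loop space."""

    origin: np.ndarray   # corner of cell (0,0,0)
    cube_length: float
    n_cells: int         # cubes per axis

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))
        if self.cube_length <= 0 or self.n_cells < 1:
            raise ParameterError("lattice needs positive cube length and cell count")

    @classmethod
    def centered(cls, center, cube_length: float, n_cells: int) -> "LatticeSpec":
        center = np.asarray(center, dtype=float).reshape(3)
        origin = center - 0.5 * cube_length * n_cells
        return cls(origin=origin, cube_length=cube_length, n_cells=n_cells)

    @property
    def n_cubes_total(self) -> int:
        return self.n_cells ** 3

    def cube_index(self, p) -> tuple:
        idx = np.floor((np.asarray(p, dtype=float) - self.origin) / self.cube_length)
        return tuple(int(v) for v in idx)

    def contains(self, p) -> bool:
        idx = self.cube_index(p)
        return all(0 <= v < self.n_cells for v in idx)

    def cube_center(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.cube_length


def direction_bin(d, width: float) -> tuple:
    """Discretize a unit vector into (polar, azimuth) bins of ``width`` radians."""
    d = np.asarray(d, dtype=float)
    d = d / np.linalg.norm(d)
    polar = float(np.arccos(np.clip(d[2], -1.0, 1.0)))
    azim = float(np.mod(np.arctan2(d[1], d[0]), 2.0 * np.pi))
    return (int(polar / width), int(azim / width))


def bin_center_direction(bin_idx: tuple, width: float) -> np.ndarray:
    polar = (bin_idx[0] + 0.5) * width
    azim = (bin_idx[1] + 0.5) * width
    sp = np.sin(polar)
    return np.array([sp * np.cos(azim), sp * np.sin(azim), np.cos(polar)])


# ---------------------------------------------------------------------------
# specs and anchors

def _perpendicular(u: np.ndarray) -> np.ndarray:
    axis = np.zeros(3)
    axis[int(np.argmin(np.abs(u)))] = 1.0
    v = np.cross(u, axis)
    return v / np.linalg.norm(v)


def canonical_anchor(pivot, takeoff) -> np.ndarray:
    """Deterministic three-point seed frame for growth from (pivot, take-off).

    The frame is built so that a first residue torsion of zero sends the
    first bond exactly along the take-off vector; other torsions sweep the
    cone of angle BOND_ANGLE about the frame's incoming bond.
    """
    pivot = np.asarray(pivot, dtype=float).reshape(3)
    u = np.asarray(takeoff, dtype=float).reshape(3)
    nu = np.linalg.norm(u)
    if nu < 1e-12:
        raise ParameterError("take-off vector must be non-zero")
    u = u / nu
    nvec = _perpendicular(u)
    m = np.cos(BOND_ANGLE) * u + np.sin(BOND_ANGLE) * nvec
    b = pivot + BOND_LENGTH * m
    first = pivot + BOND_LENGTH * u  # virtual image of a zero-torsion first atom
    a = place_atom(first, pivot, b, BOND_LENGTH, BOND_ANGLE, np.pi)
    return np.vstack([a, b, pivot])


@dataclass(frozen=True)
class LoopSpec:
    """Problem statement for one loop closure.

    ``anchor1``/``anchor2`` optionally pin the full three-point seed frames
    at the pivots; when absent they are constructed canonically from
    (pivot, take-off), which fixes the torsional reference of the first
    placed atom deterministically.
    """

    pivot1: np.ndarray
    pivot2: np.ndarray
    takeoff1: np.ndarray
    takeoff2: np.ndarray
    k: int
    lattice: LatticeSpec
    angle_tol: float = 0.2
    anchor1: np.ndarray = None
    anchor2: np.ndarray = None

    def __post_init__(self):
        for name in ("pivot1", "pivot2", "takeoff1", "takeoff2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if self.k < 2:
            raise ParameterError("a loop needs at least 2 residues")
        if self.angle_tol <= 0:
            raise ParameterError("angle tolerance must be positive")
        for name in ("anchor1", "anchor2"):
            val = getattr(self, name)
            if val is not None:
                object.__setattr__(self, name, np.asarray(val, dtype=float).reshape(3, 3))
        for piv in (self.pivot1, self.pivot2):
            if not self.lattice.contains(piv):
                raise ConfigurationError("both pivots must lie inside the lattice")

    def anchor(self, side: int) -> np.ndarray:
        if side == 1:
            return self.anchor1 if self.anchor1 is not None else canonical_anchor(self.pivot1, self.takeoff1)
        if side == 2:
            return self.anchor2 if self.anchor2 is not None else canonical_anchor(self.pivot2, self.takeoff2)
        raise ParameterError("side must be 1 or 2")

    @property
    def depths(self) -> tuple:
        """Residues grown per side: side 1 takes the longer half of odd k."""
        m1 = (self.k + 1) // 2
        return m1, self.k - m1

    @property
    def bin_width(self) -> float:
        # tied to the tolerance so collapsing cannot merge states that later
        # fail the angle check by more than the tolerance itself
        return self.angle_tol / 2.0


# ---------------------------------------------------------------------------
# residue conformations

_CANON_ANCHOR = None


def _canonical_residue_anchor() -> np.ndarray:
    global _CANON_ANCHOR
    if _CANON_ANCHOR is None:
        _CANON_ANCHOR = canonical_anchor(np.zeros(3), np.array([1.0, 0.0, 0.0]))
    return _CANON_ANCHOR


@dataclass(frozen=True)
class ResidueConformation:
    """One sampled residue: its two torsions and its relative end frame.

    The end frame (position of the residue's terminal junction atom and the
    direction of the last bond) is stored in the canonical residue frame;
    ``encoded_id`` packs the discretized (cube offset, direction bin) into
    a single integer.
    """

    conf_id: int
    phi: float
    psi: float
    end_pos: np.ndarray
    end_dir: np.ndarray
    encoded_id: int = -1


def _residue_end_frame(phi: float, psi: float):
    anchor = _canonical_residue_anchor()
    ca = place_atom(anchor[0], anchor[1], anchor[2], BOND_LENGTH, BOND_ANGLE, phi)
    j = place_atom(anchor[1], anchor[2], ca, BOND_LENGTH, BOND_ANGLE, psi)
    return ca, j


def precompute_conformations(
    sampler,
    seed: int = 0,
    lattice_pitch: float = 0.5,
    angle_tol: float = 0.2,
) -> list:
    """Build the single-residue conformation table.

    ``sampler`` is either an integer Mr (that many torsion pairs drawn
    uniformly at random, seeded), a pair of per-torsion sample lists (full
    product grid -- the representation that makes reversed chains exactly
    representable), or an explicit list of (phi, psi) pairs.  Each entry's
    end frame is discretized on ``lattice_pitch`` cubes and angle bins of
    ``angle_tol/2`` to produce a unique integer encoding.
    """
    if isinstance(sampler, (int, np.integer)):
        if sampler < 1:
            raise ParameterError("need at least one conformation")
        rng = np.random.default_rng(seed)
        pairs = rng.uniform(0.0, 2.0 * np.pi, size=(int(sampler), 2))
    elif (
        isinstance(sampler, (tuple, list))
        and len(sampler) == 2
        and np.ndim(sampler[0]) == 1
        and np.ndim(sampler[1]) == 1
    ):
        pairs = np.array(list(itertools.product(np.asarray(sampler[0], dtype=float),
                                                np.asarray(sampler[1], dtype=float))))
    else:
        pairs = np.asarray(sampler, dtype=float).reshape(-1, 2)
    width = angle_tol / 2.0
    table = []
    codes = {}
    for cid, (phi, psi) in enumerate(pairs):
        ca, j = _residue_end_frame(float(phi), float(psi))
        end_dir = (j - ca) / np.linalg.norm(j - ca)
        cube = tuple(int(v) for v in np.floor(j / lattice_pitch))
        dbin = direction_bin(end_dir, width)
        key = (cube, dbin)
        code = codes.setdefault(key, len(codes))
        table.append(
            ResidueConformation(
                conf_id=cid, phi=float(phi), psi=float(psi),
                end_pos=j, end_dir=end_dir, encoded_id=code,
            )
        )
    return table


def residues_connect(
    end_pos, end_dir, begin_pos, next_bond_dir, lattice: LatticeSpec, angle_tol: float
) -> bool:
    """Can a residue ending at (end_pos, end_dir) continue into one starting
    at ``begin_pos`` with first bond along ``next_bond_dir``?

    True iff the two junction atoms share a lattice cube and the bond angle
    they would form deviates from the ideal by at most ``angle_tol``.
    """
    if lattice.cube_index(end_pos) != lattice.cube_index(begin_pos):
        return False
    ang = float(np.arccos(np.clip(
        np.dot(-np.asarray(end_dir, dtype=float), np.asarray(next_bond_dir, dtype=float)),
        -1.0, 1.0,
    )))
    return abs(ang - BOND_ANGLE) <= angle_tol


def build_connectivity(table, lattice: LatticeSpec, angle_tol: float) -> np.ndarray:
    """Pairwise compatibility of table entries under discretized composition.

    Entry (i, j) is True when conformation j, grown on conformation i's
    *discretized* end frame (cube-snapped junction position, bin-center
    last-bond direction), still lands its first bond within ``angle_tol``
    of the ideal bond angle at a shared-cube junction relative to i's exact
    geometry.  The relation never excludes an exact geometric continuation,
    so filtering growth through it cannot lose valid loops.
    """
    width = angle_tol / 2.0
    mr = len(table)
    anchor = _canonical_residue_anchor()
    out = np.zeros((mr, mr), dtype=bool)
    for i, c1 in enumerate(table):
        ca1 = c1.end_pos - BOND_LENGTH * c1.end_dir
        snapped_dir = bin_center_direction(direction_bin(c1.end_dir, width), width)
        snapped_ca = c1.end_pos - BOND_LENGTH * snapped_dir
        for j, c2 in enumerate(table):
            ca2 = place_atom(anchor[2], snapped_ca, c1.end_pos,
                             BOND_LENGTH, BOND_ANGLE, c2.phi)
            first_bond = (ca2 - c1.end_pos) / BOND_LENGTH
            out[i, j] = residues_connect(
                c1.end_pos, c1.end_dir, c1.end_pos, first_bond, lattice, angle_tol
            )
    return out


# ---------------------------------------------------------------------------
# growth

@dataclass
class SemiLoopState:
    """A collapsed chain end: one state per (cube, direction bin) per depth."""

    key: tuple                 # (cube index triple, direction bin pair)
    tail: np.ndarray           # exemplar last three chain atoms, (3, 3)
    depth: int
    preds: list = field(default_factory=list)  # [(predecessor key, conf_id), ...]
    last_conf: int = -1


def _state_key(lattice: LatticeSpec, width: float, end_pos, end_dir) -> tuple:
    return (lattice.cube_index(end_pos), direction_bin(end_dir, width))


def grow_semiloop(
    spec: LoopSpec,
    side: int,
    depth: int,
    table,
    connectivity: np.ndarray = None,
    multi_pred: bool = True,
) -> list:
    """Grow one semi-loop to ``depth`` residues; returns per-depth state dicts.

    Each step extends every surviving state by every table conformation
    (optionally filtered through the connectivity relation), discards ends
    leaving the lattice, and collapses states per (cube, direction-bin)
    key.  The first extension reaching a key (in deterministic scan order)
    provides the exemplar coordinates; with ``multi_pred`` every
    predecessor link is retained for exhaustive backtracking, otherwise
    only the exemplar's.
    """
    lattice = spec.lattice
    width = spec.bin_width
    anchor = spec.anchor(side)
    pivot = spec.pivot1 if side == 1 else spec.pivot2
    takeoff = spec.takeoff1 if side == 1 else spec.takeoff2
    if not lattice.contains(pivot):
        raise ConfigurationError("pivot lies outside the lattice")
    seed = SemiLoopState(
        key=_state_key(lattice, width, pivot, takeoff),
        tail=anchor.copy(),
        depth=0,
    )
    levels = [{seed.key: seed}]
    for d in range(1, depth + 1):
        nxt = {}
        for key in sorted(levels[-1]):
            state = levels[-1][key]
            conf_ids = range(len(table))
            if connectivity is not None and state.last_conf >= 0:
                conf_ids = np.flatnonzero(connectivity[state.last_conf])
            for cid in conf_ids:
                conf = table[cid]
                a, b, c = state.tail
                ca = place_atom(a, b, c, BOND_LENGTH, BOND_ANGLE, conf.phi)
                j = place_atom(b, c, ca, BOND_LENGTH, BOND_ANGLE, conf.psi)
                if not (lattice.contains(ca) and lattice.contains(j)):
                    continue
                end_dir = (j - ca) / BOND_LENGTH
                k2 = _state_key(lattice, width, j, end_dir)
                if k2 in nxt:
                    if multi_pred:
                        nxt[k2].preds.append((key, cid))
                else:
                    nxt[k2] = SemiLoopState(
                        key=k2,
                        tail=np.vstack([c, ca, j]),
                        depth=d,
                        preds=[(key, cid)],
                        last_conf=cid,
                    )
        levels.append(nxt)
    return levels


def instantiate_chain(anchor, conf_ids, table) -> np.ndarray:
    """Exact Cartesian re-instantiation of a conformation-id sequence.

    Returns the chain atoms starting at the pivot junction: the pivot plus
    (Cα, junction) per residue -- 2k+1 points for k residues.
    """
    anchor = np.asarray(anchor, dtype=float).reshape(3, 3)
    atoms = [anchor[2]]
    frame = [anchor[0], anchor[1], anchor[2]]
    for cid in conf_ids:
        conf = table[cid]
        ca = place_atom(frame[-3], frame[-2], frame[-1], BOND_LENGTH, BOND_ANGLE, conf.phi)
        j = place_atom(frame[-2], frame[-1], ca, BOND_LENGTH, BOND_ANGLE, conf.psi)
        atoms.extend([ca, j])
        frame.extend([ca, j])
    return np.asarray(atoms)


@dataclass(frozen=True)
class LoopResult:
    """A closed loop that survived exact final validation.

    ``atoms`` runs pivot 1 -> pivot 2 with (Cα, junction) pairs per residue;
    ``mid_gap`` is the Cartesian distance between the two semi-loop ends
    that were identified at the midpoint (bounded by the cube diagonal).
    """

    atoms: np.ndarray
    conf_ids_1: tuple
    conf_ids_2: tuple
    mid_gap: float
    max_angle_dev: float


def _backtrack_paths(levels, final_key, max_paths=None):
    """Yield conformation-id sequences (pivot -> end) reaching ``final_key``."""

    def walk(depth, key):
        if depth == 0:
            yield ()
            return
        state = levels[depth].get(key)
        if state is None:
            return
        for prev_key, cid in state.preds:
            for prefix in walk(depth - 1, prev_key):
                yield prefix + (cid,)

    yield from walk(len(levels) - 1, final_key)


def _loop_junction_stats(atoms: np.ndarray):
    """Max deviation of interior junction bond angles from the ideal."""
    devs = [0.0]
    for j in range(2, len(atoms) - 2, 2):
        ang = bond_angle(atoms[j - 1], atoms[j], atoms[j + 1])
        devs.append(abs(ang - BOND_ANGLE))
    return max(devs)


def match_and_backtrack(
    levels1,
    levels2,
    spec: LoopSpec,
    table,
    max_results: int = 0,
) -> list:
    """Match the two growths in the middle and emit validated closed loops.

    Semi-loop end states match when they share a lattice cube; matched key
    pairs are screened by the junction angle of their exemplars (with slack
    for the discretization) and then backtracked.  Every candidate loop is
    re-instantiated exactly from both pivot anchors and emitted only if the
    assembled loop passes exact re-measurement: all junction bond angles
    within ``angle_tol`` of the ideal and the two midpoint ends inside the
    same cube.  Enumeration is deterministic; ``max_results`` stops early
    (0 = all).
    """
    lattice = spec.lattice
    # screening slack: direction bins and cube snapping can shift the exemplar
    # angle relative to the best path through the same key
    slack = 2.0 * spec.bin_width + 2.0 * np.arcsin(
        min(1.0, np.sqrt(3.0) * lattice.cube_length / (2.0 * BOND_LENGTH))
    )
    final1 = levels1[-1]
    final2 = levels2[-1]
    by_cube = {}
    for key in sorted(final2):
        by_cube.setdefault(key[0], []).append(key)
    results = []
    for key1 in sorted(final1):
        state1 = final1[key1]
        for key2 in by_cube.get(key1[0], ()):
            state2 = final2[key2]
            mid1, prev1 = state1.tail[2], state1.tail[1]
            mid2, prev2 = state2.tail[2], state2.tail[1]
            ang = bond_angle(prev1, mid1, prev2 + (mid1 - mid2))
            if abs(ang - BOND_ANGLE) > spec.angle_tol + slack:
                continue
            for path1 in _backtrack_paths(levels1, key1):
                chain1 = instantiate_chain(spec.anchor(1), path1, table)
                for path2 in _backtrack_paths(levels2, key2):
                    chain2 = instantiate_chain(spec.anchor(2), path2, table)
                    end1, end2 = chain1[-1], chain2[-1]
                    if lattice.cube_index(end1) != lattice.cube_index(end2):
                        continue
                    # assemble: side 1 atoms, then side 2 reversed minus its end,
                    # identifying the midpoint junction with side 1's copy
                    atoms = np.vstack([chain1, chain2[:-1][::-1]])
                    max_dev = _loop_junction_stats(atoms)
                    if max_dev > spec.angle_tol:
                        continue
                    results.append(
                        LoopResult(
                            atoms=atoms,
                            conf_ids_1=tuple(path1),
                            conf_ids_2=tuple(path2),
                            mid_gap=float(np.linalg.norm(end1 - end2)),
                            max_angle_dev=float(max_dev),
                        )
                    )
                    if max_results and len(results) >= max_results:
                        return results
    return results
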