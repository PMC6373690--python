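"""Adaptive two-tree descent for one pattern edge.

Walks two octrees level-synchronously, pruning cube pairs that cannot
contain a point pair at the target distance (necessary condition) and
accepting leaf pairs whose every interior point pair is guaranteed within
tolerance (sufficient condition).  An approximation margin eta trades a
slice of the tolerance for speed: matches within (1-eta)*eps_T of the
target length are guaranteed found.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ParameterError
from .octree import Octree, OctreeNode

__all__ = [
    "SQRT3",
    "ToleranceModel",
    "CubePair",
    "EdgeMatchSet",
    "necessary_condition",
    "sufficient_condition",
    "adaptive_pair_search",
    "pruning_profile",
]

SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class ToleranceModel:
    """Search tolerance eps_T and approximation margin eta.

    The minimum leaf side defaults to ``eta * eps_T / (4*sqrt(3))``, the
    value for which the completeness guarantee holds; acceptance via the
    sufficient condition additionally requires ``ls <= eps_T / (2*sqrt(3))``.
    """

    eps_T: float
    eta: float = 0.5
    ls_override: float = None

    def __post_init__(self):
        if self.eps_T < 0:
            raise ParameterError("eps_T must be non-negative")
        if not (0.0 < self.eta < 1.0):
            raise ParameterError("eta must lie strictly in (0, 1)")
        if self.ls_override is not None and self.ls_override <= 0:
            raise ParameterError("ls override must be positive")

    @property
    def ls(self) -> float:
        if self.ls_override is not None:
            return float(self.ls_override)
        return self.eta * self.eps_T / (4.0 * SQRT3)

    @property
    def leaf_bound(self) -> float:
        """Largest admissible minimum leaf side for sufficient-condition acceptance."""
        return self.eps_T / (2.0 * SQRT3)

    def check_leaf_bound(self) -> None:
        if self.ls > self.leaf_bound + 1e-12:
            raise ParameterError(
                f"ls={self.ls:g} exceeds eps_T/(2*sqrt(3))={self.leaf_bound:g}; "
                "the sufficient condition could never fire"
            )


def _pair_radius(a, b) -> float:
    # worst-case center-to-point deviation: half diagonal of each cube
    return (SQRT3 / 2.0) * (a.side + b.side)


def _center_distance(a, b) -> float:
    return float(np.linalg.norm(a.center - b.center))


def necessary_condition(a, b, target: float, eps_T: float) -> bool:
    """Can cubes ``a`` and ``b`` possibly contain a point pair at ``target`` ± eps_T?

    Rejects (returns False) when the center distance d satisfies
    ``d < target - eps_T - r`` or ``d > target + eps_T + r`` with
    ``r = (sqrt(3)/2)(side_a + side_b)`` (= sqrt(3)*l for equal sides l).
    A rejected pair provably contains no qualifying point pair.
    """
    if target < 0 or eps_T < 0:
        raise ParameterError("target length and eps_T must be non-negative")
    cube_a = a.cube if isinstance(a, OctreeNode) else a
    cube_b = b.cube if isinstance(b, OctreeNode) else b
    r = _pair_radius(cube_a, cube_b)
    d = _center_distance(cube_a, cube_b)
    return (target - eps_T - r) <= d <= (target + eps_T + r)


def sufficient_condition(a, b, target: float, eps_T: float) -> bool:
    """Is every point pair drawn from ``a`` x ``b`` within eps_T of ``target``?

    True iff ``target - eps_T + r <= d <= target + eps_T - r``; the window
    is empty (always False) once the cube sides exceed eps_T/sqrt(3).
    """
    if target < 0 or eps_T < 0:
        raise ParameterError("target length and eps_T must be non-negative")
    cube_a = a.cube if isinstance(a, OctreeNode) else a
    cube_b = b.cube if isinstance(b, OctreeNode) else b
    r = _pair_radius(cube_a, cube_b)
    d = _center_distance(cube_a, cube_b)
    return (target - eps_T + r) <= d <= (target + eps_T - r)


@dataclass(frozen=True)
class CubePair:
    """A surviving pair of nodes with its center distance and classification."""

    a: OctreeNode
    b: OctreeNode
    center_distance: float
    status: str  # "possible" | "accepted" | "rejected"


@dataclass
class EdgeMatchSet:
    """Outcome of the two-tree search for one polygon edge (i, j).

    ``accepted_pairs`` passed the sufficient condition: every interior point
    pair qualifies wholesale.  ``boundary_pairs`` passed only the necessary
    condition at leaf level; with exact refinement on, ``verified_pairs``
    stores the individual qualifying point-index pairs found inside them.
    """

    edge: tuple
    target_length: float
    accepted_pairs: list = field(default_factory=list)
    boundary_pairs: list = field(default_factory=list)
    verified_pairs: dict = field(default_factory=dict)  # boundary idx -> [(pi, qj), ...]
    refined: bool = True
    tree_a: Octree = None
    tree_b: Octree = None

    @property
    def sij(self) -> int:
        """Count of leaf pairs contributing matches (the s_ij selectivity statistic)."""
        n = len(self.accepted_pairs)
        if self.refined:
            n += sum(1 for v in self.verified_pairs.values() if v)
        return n

    def iter_point_pairs(self):
        """Yield all (point_index_in_tree_a, point_index_in_tree_b) matches."""
        for pair in self.accepted_pairs:
            for pi in pair.a.point_idx:
                for qj in pair.b.point_idx:
                    yield int(pi), int(qj)
        if self.refined:
            for pairs in self.verified_pairs.values():
                yield from pairs


def _expand(node: OctreeNode):
    # a node that is already a leaf self-pairs downward unchanged
    return node.children if node.children else [node]


def _descend(t1: Octree, t2: Octree, target: float, eps_T: float):
    """Generator of per-level frontiers of possible pairs (root pair first)."""
    if abs(t1.l0 - t2.l0) > 1e-9:
        raise ConfigurationError(
            f"co-searched trees must share l0 (got {t1.l0} and {t2.l0})"
        )
    frontier = []
    if necessary_condition(t1.root, t2.root, target, eps_T):
        frontier = [(t1.root, t2.root)]
    yield frontier
    while frontier and any(not (a.is_leaf and b.is_leaf) for a, b in frontier):
        nxt = []
        for a, b in frontier:
            for ca in _expand(a):
                for cb in _expand(b):
                    if necessary_condition(ca, cb, target, eps_T):
                        nxt.append((ca, cb))
        nxt.sort(key=lambda p: (p[0].path, p[1].path))
        frontier = nxt
        yield frontier


def adaptive_pair_search(
    t1: Octree,
    t2: Octree,
    target: float,
    tol: ToleranceModel,
    edge: tuple = (0, 1),
    cube_approx: bool = False,
) -> EdgeMatchSet:
    """Find all leaf-cube pairs that can host point pairs at ``target`` ± eps_T.

    Level-synchronous breadth-first descent: only children of surviving
    pairs are examined.  At leaf level, pairs passing the sufficient
    condition are accepted wholesale.  Pairs that passed only the necessary
    condition are, by default, refined by exact point-level distance checks
    (soundness-first).  With ``cube_approx=True`` they are dropped instead,
    reproducing the coarser approximation semantics: every match within
    (1-eta)*eps_T is still guaranteed found, but matches in the outer
    tolerance band may be missed.
    """
    tol.check_leaf_bound()
    for t in (t1, t2):
        if t.min_side - 1e-12 > tol.ls:
            raise ConfigurationError(
                f"tree built with ls={t.min_side:g} coarser than the tolerance model's ls={tol.ls:g}"
            )
    frontier = None
    for frontier in _descend(t1, t2, target, tol.eps_T):
        pass
    result = EdgeMatchSet(
        edge=tuple(edge),
        target_length=float(target),
        refined=not cube_approx,
        tree_a=t1,
        tree_b=t2,
    )
    if frontier is None:
        return result
    for a, b in frontier:
        d = _center_distance(a.cube, b.cube)
        if sufficient_condition(a, b, target, tol.eps_T):
            result.accepted_pairs.append(CubePair(a, b, d, "accepted"))
        else:
            pair = CubePair(a, b, d, "possible")
            result.boundary_pairs.append(pair)
    if not cube_approx:
        for k, pair in enumerate(result.boundary_pairs):
            pa = t1.points[pair.a.point_idx]
            pb = t2.points[pair.b.point_idx]
            dist = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
            ok = np.argwhere(np.abs(dist - target) <= tol.eps_T)
            result.verified_pairs[k] = [
                (int(pair.a.point_idx[i]), int(pair.b.point_idx[j])) for i, j in ok
            ]
    return result


def pruning_profile(t1: Octree, t2: Octree, target: float, tol: ToleranceModel) -> list:
    """Per-level surviving cube-pair and implied candidate point-pair counts.

    Diagnostic mirror of the search's own frontier; the candidate point-pair
    count is the sum of |points(a)| * |points(b)| over surviving pairs and
    decreases (at least) geometrically on typical clouds.
    """
    profile = []
    for level, frontier in enumerate(_descend(t1, t2, target, tol.eps_T)):
        n_pts = sum(a.n_points * b.n_points for a, b in frontier)
        profile.append({"level": level, "cube_pairs": len(frontier), "point_pairs": n_pts})
    return profile
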