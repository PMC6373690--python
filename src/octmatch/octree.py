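"""Adaptive octree decomposition of a point cloud.

A node splits only while its cube side is at least twice the minimum leaf
side ``ls``, so every leaf has side in [ls, 2*ls).  Empty children are
discarded during construction, and points landing exactly on a splitting
plane go deterministically to the higher-index octant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import OutOfBoundsError, ParameterError
from .manifold import Manifold

__all__ = ["Cube", "OctreeNode", "Octree", "build_octree", "common_root_side"]

# child octant index: bit 0 = x high, bit 1 = y high, bit 2 = z high
_OFFSETS = np.array(
    [[(i >> a) & 1 for a in range(3)] for i in range(8)], dtype=float
) - 0.5


@dataclass(frozen=True)
class Cube:
    """An axis-aligned cube: center, side length and tree depth."""

    center: np.ndarray
    side: float
    level: int

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if self.side <= 0:
            raise ParameterError("cube side must be positive")

    def contains(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        half = self.side / 2.0
        return np.all(np.abs(pts - self.center) <= half + 1e-12, axis=1)

    @property
    def corners(self) -> np.ndarray:
        return self.center + self.side * _OFFSETS


class OctreeNode:
    """One retained (non-empty) node of the hierarchy."""

    __slots__ = ("cube", "children", "point_idx", "path")

    def __init__(self, cube: Cube, point_idx: np.ndarray, path: tuple):
        self.cube = cube
        self.children: list[OctreeNode] = []
        self.point_idx = point_idx
        self.path = path

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def n_points(self) -> int:
        return len(self.point_idx)

    def __repr__(self):  # pragma: no cover - debug aid
        kind = "leaf" if self.is_leaf else f"{len(self.children)} children"
        return f"<OctreeNode path={self.path} side={self.cube.side:g} n={self.n_points} {kind}>"


class Octree:
    """Hierarchical cube decomposition over a fixed point cloud.

    Every input point lives in exactly one leaf; leaf sides fall in
    [ls, 2*ls); the structure is a deterministic function of its inputs.
    """

    def __init__(self, root: OctreeNode, points: np.ndarray, l0: float, ls: float):
        self.root = root
        self.points = points
        self.l0 = l0
        self.min_side = ls

    @property
    def n_points(self) -> int:
        return len(self.points)

    def leaves(self) -> list:
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend(reversed(node.children))
        return out

    def nodes_at_level(self, level: int) -> list:
        """All retained nodes whose depth equals ``level`` (with point counts)."""
        if level < 0:
            raise ParameterError("level must be non-negative")
        out = []
        frontier = [self.root]
        for _ in range(level):
            nxt = []
            for node in frontier:
                nxt.extend(node.children)
            frontier = nxt
        for node in frontier:
            out.append((node.cube, node.n_points))
        return out

    def frontier_at_level(self, level: int) -> list:
        """Nodes at ``level``, with shallower leaves carried down unchanged.

        This is the level-synchronous view the pair search walks: a branch
        that already terminated keeps representing its leaf at every deeper
        level, so the frontier always partitions the full point set.
        """
        frontier = [self.root]
        for _ in range(level):
            nxt = []
            for node in frontier:
                nxt.extend(node.children if node.children else [node])
            frontier = nxt
        return frontier

    @property
    def depth(self) -> int:
        best = 0
        stack = [(self.root, 0)]
        while stack:
            node, d = stack.pop()
            best = max(best, d)
            stack.extend((c, d + 1) for c in node.children)
        return best

    def to_json(self, path=None) -> str:
        """Debug dump of the hierarchy (center, side, count per node)."""

        def encode(node):
            doc = {
                "center": node.cube.center.tolist(),
                "side": node.cube.side,
                "level": node.cube.level,
                "count": node.n_points,
            }
            if node.children:
                doc["children"] = [encode(c) for c in node.children]
            return doc

        text = json.dumps(encode(self.root), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def common_root_side(manifolds, ls: float) -> float:
    """Smallest power-of-two multiple of ls whose cube covers every manifold.

    Co-searched trees must share one initial cube length l0 so that level k
    of one tree is geometrically comparable with level k of another.
    """
    if ls <= 0:
        raise ParameterError("ls must be positive")
    extent = 0.0
    for man in manifolds:
        pts = man.points if isinstance(man, Manifold) else np.asarray(man, dtype=float)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        extent = max(extent, float((hi - lo).max()))
    k = max(0, int(np.ceil(np.log2(max(extent, ls) / ls))))
    l0 = ls * (2 ** k)
    # bounding boxes are centered on the root, so cover needs l0 >= extent
    while l0 < extent:
        l0 *= 2  # pragma: no cover - guard against float edge cases
    return l0


def build_octree(man, l0: float, ls: float, origin=None) -> Octree:
    """Build the adaptive octree over a manifold (or bare point array).

    ``origin`` defaults to the cloud's bounding-box centroid.  All points
    must lie inside the root cube of side ``l0``.
    """
    pts = man.points if isinstance(man, Manifold) else np.atleast_2d(np.asarray(man, dtype=float))
    if ls <= 0:
        raise ParameterError("minimum leaf side ls must be positive")
    if l0 < ls:
        raise ParameterError(f"root side l0={l0} must be at least ls={ls}")
    if origin is None:
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        origin = (lo + hi) / 2.0
    origin = np.asarray(origin, dtype=float).reshape(3)
    half = l0 / 2.0
    outside = np.any(np.abs(pts - origin) > half + 1e-12, axis=1)
    if outside.any():
        bad = pts[int(np.argmax(outside))]
        raise OutOfBoundsError(f"point {bad.tolist()} lies outside the root cube (l0={l0})")

    def grow(center, side, level, idx, path):
        node = OctreeNode(Cube(center, side, level), idx, path)
        if side < 2 * ls:
            return node
        sub = pts[idx]
        # octant by sign of offset; ties (points on a splitting plane) go high
        high = sub >= center
        codes = high[:, 0].astype(int) | (high[:, 1].astype(int) << 1) | (high[:, 2].astype(int) << 2)
        for oct_idx in range(8):
            child_idx = idx[codes == oct_idx]
            if len(child_idx) == 0:
                continue
            child_center = center + (side / 2.0) * _OFFSETS[oct_idx]
            node.children.append(
                grow(child_center, side / 2.0, level + 1, child_idx, path + (oct_idx,))
            )
        node.point_idx = idx
        return node

    root = grow(origin, float(l0), 0, np.arange(len(pts)), ())
    return Octree(root, pts, float(l0), float(ls))
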