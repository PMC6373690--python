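"""Combining per-edge match sets into full n-tuples.

Each pattern edge (i, j) yields a set of compatible leaf-cube pairs from
trees t_i and t_j.  A desirable configuration is an n-tuple of leaf cubes,
one per tree, consistent with *all* n(n-1)/2 edge sets simultaneously --
realized here as sparse boolean joins over cube-index pairs rather than a
dense matrix product.  An optional strongly-connected-component prefilter
over the n-cycle of groups removes cubes that cannot take part in any tuple.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import IncompleteInputError
from .geometry import TargetPolygon, polygon_error
from .pair_search import ToleranceModel

__all__ = ["MatchGraph", "ConfigurationResult", "assemble", "scc_prefilter"]


@dataclass(frozen=True)
class ConfigurationResult:
    """One desirable n-tuple: leaf-cube paths, representative points, realized error."""

    cube_paths: tuple
    points: np.ndarray
    epsilon: float
    verified: bool


@dataclass
class MatchGraph:
    """Leaf cubes as vertices, per-edge cube pairs as edges.

    ``vertices[i]`` holds the leaf paths of tree i that appear in at least
    one admitted pair; ``edges[(i, j)]`` (i < j) holds the admitted
    (path_i, path_j) pairs for that pattern edge.
    """

    n: int
    vertices: dict = field(default_factory=dict)
    edges: dict = field(default_factory=dict)

    @classmethod
    def from_edge_sets(cls, edge_sets: dict) -> "MatchGraph":
        n = max(max(e) for e in edge_sets) + 1
        g = cls(n=n, vertices={i: set() for i in range(n)}, edges={})
        for (i, j), ems in edge_sets.items():
            pairs = set()
            for pair in ems.accepted_pairs:
                pairs.add((pair.a.path, pair.b.path))
            if ems.refined:
                for k, pair in enumerate(ems.boundary_pairs):
                    if ems.verified_pairs.get(k):
                        pairs.add((pair.a.path, pair.b.path))
            g.edges[(i, j)] = pairs
            for pa, pb in pairs:
                g.vertices[i].add(pa)
                g.vertices[j].add(pb)
        return g


def scc_prefilter(g: MatchGraph) -> MatchGraph:
    """Restrict the match graph to strongly connected components spanning all groups.

    Edges are oriented around the n-cycle of groups t1 -> t2 -> ... -> tn -> t1;
    any valid n-tuple traces a directed cycle through all n groups, so its
    cubes sit inside one SCC touching every group.  Cubes outside such
    components can therefore be dropped without losing any tuple.
    """
    n = g.n
    dg = nx.DiGraph()
    for i, verts in g.vertices.items():
        for v in verts:
            dg.add_node((i, v))
    for i in range(n):
        j = (i + 1) % n
        key = (min(i, j), max(i, j))
        for pa, pb in g.edges.get(key, ()):
            if key[0] == i:
                dg.add_edge((i, pa), (j, pb))
            else:
                dg.add_edge((i, pb), (j, pa))
    keep = set()
    for comp in nx.strongly_connected_components(dg):
        groups = {i for i, _ in comp}
        if len(groups) == n:
            keep |= comp
    out = MatchGraph(n=n, vertices={i: set() for i in range(n)}, edges={})
    for i, verts in g.vertices.items():
        out.vertices[i] = {v for v in verts if (i, v) in keep}
    for key, pairs in g.edges.items():
        i, j = key
        out.edges[key] = {
            (pa, pb) for pa, pb in pairs if (i, pa) in keep and (j, pb) in keep
        }
    return out


def _normalize_edge_sets(edge_sets) -> dict:
    if isinstance(edge_sets, dict):
        items = list(edge_sets.items())
    else:
        items = [(ems.edge, ems) for ems in edge_sets]
    out = {}
    for edge, ems in items:
        i, j = edge
        if i == j:
            raise IncompleteInputError(f"degenerate edge {edge}")
        out[(min(i, j), max(i, j))] = ems
    return out


def assemble(
    edge_sets,
    target: TargetPolygon,
    tol: ToleranceModel,
    limit: int = 0,
    verify_points: bool = True,
    exhaustive_points: bool = False,
    prefilter: bool = False,
) -> list:
    """Join all edge match sets into desirable n-tuples of leaf cubes.

    Cube tuples are enumerated deterministically (sorted leaf paths),
    seeding from the edge with the fewest surviving pairs -- the standard
    selectivity heuristic.  With ``verify_points`` on, each cube tuple is
    reported through an actual qualifying point selection (the first found
    in a deterministic scan) together with its realized error; pass
    ``exhaustive_points=True`` to emit every qualifying point tuple inside
    each cube tuple instead.  ``limit`` stops after that many results
    (0 = all).  Output is invariant to the input order of the edge sets.
    """
    sets = _normalize_edge_sets(edge_sets)
    n = target.n
    required = {(i, j) for i in range(n) for j in range(i + 1, n)}
    missing = required - set(sets)
    if missing:
        raise IncompleteInputError(f"missing edge match sets for {sorted(missing)}")

    graph = MatchGraph.from_edge_sets(sets)
    if prefilter and n >= 3:
        graph = scc_prefilter(graph)

    # per-tree coordinate arrays and leaf-node lookup
    tree_points = {}
    leaf_nodes = {i: {} for i in range(n)}
    for (i, j), ems in sets.items():
        if ems.tree_a is not None:
            tree_points[i] = ems.tree_a.points
        if ems.tree_b is not None:
            tree_points[j] = ems.tree_b.points
        for pair in ems.accepted_pairs + ems.boundary_pairs:
            leaf_nodes[i][pair.a.path] = pair.a
            leaf_nodes[j][pair.b.path] = pair.b

    # adjacency and per-pair point restrictions (None = all interior pairs)
    adj = {}
    restrictions = {}
    for (i, j), ems in sets.items():
        restr = {}
        for pair in ems.accepted_pairs:
            restr[(pair.a.path, pair.b.path)] = None
        if ems.refined:
            for k, pair in enumerate(ems.boundary_pairs):
                verified = ems.verified_pairs.get(k)
                if verified:
                    restr[(pair.a.path, pair.b.path)] = set(verified)
        if prefilter and n >= 3:
            restr = {
                pp: v
                for pp, v in restr.items()
                if pp[0] in graph.vertices[i] and pp[1] in graph.vertices[j]
            }
        restrictions[(i, j)] = restr
        fwd, bwd = {}, {}
        for pa, pb in restr:
            fwd.setdefault(pa, set()).add(pb)
            bwd.setdefault(pb, set()).add(pa)
        adj[(i, j)] = fwd
        adj[(j, i)] = bwd

    seed_edge = min(sets, key=lambda e: (sets[e].sij, e))
    order = [seed_edge[0], seed_edge[1]] + sorted(
        i for i in range(n) if i not in seed_edge
    )

    results = []
    stop = False

    def candidates(tree_idx, assigned):
        cands = None
        for j, path_j in assigned.items():
            partners = adj[(j, tree_idx)].get(path_j, set())
            cands = set(partners) if cands is None else (cands & partners)
            if not cands:
                return set()
        return cands if cands is not None else set(graph.vertices[tree_idx])

    def qualifying_point_tuples(paths):
        per_tree_points = [
            [int(p) for p in leaf_nodes[i][paths[i]].point_idx] for i in range(n)
        ]
        for combo in itertools.product(*per_tree_points):
            ok = True
            for (i, j), restr in restrictions.items():
                allowed = restr.get((paths[i], paths[j]))
                if allowed is not None and (combo[i], combo[j]) not in allowed:
                    ok = False
                    break
            if ok:
                yield combo

    def emit(assigned):
        nonlocal stop
        paths = {i: assigned[i] for i in range(n)}
        tuple_paths = tuple(paths[i] for i in range(n))
        if not verify_points:
            reps = np.array([leaf_nodes[i][paths[i]].cube.center for i in range(n)])
            results.append(
                ConfigurationResult(tuple_paths, reps, polygon_error(reps, target), False)
            )
            stop = bool(limit) and len(results) >= limit
            return
        for combo in qualifying_point_tuples(paths):
            pts = np.array([tree_points[i][combo[i]] for i in range(n)])
            eps = polygon_error(pts, target)
            if eps <= tol.eps_T + 1e-12:
                results.append(ConfigurationResult(tuple_paths, pts, eps, True))
                if limit and len(results) >= limit:
                    stop = True
                    return
                if not exhaustive_points:
                    return

    def backtrack(pos, assigned):
        if stop:
            return
        if pos == len(order):
            emit(assigned)
            return
        i = order[pos]
        for path in sorted(candidates(i, assigned)):
            assigned[i] = path
            backtrack(pos + 1, assigned)
            del assigned[i]
            if stop:
                return

    if all(graph.vertices.get(i) for i in range(n)):
        backtrack(0, {})
    return results
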