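"""Synthetic fixtures with planted ground truth.

Everything here is a pure function of (parameters, seed), so tests and the
acceptance checks never need external data: point clouds with one planted
match among uniform decoys, a toy scaffold library containing one
known-answer scaffold built as a rigid copy of the hotspot stubs, and
closable loop specs whose planted loop is exactly representable by the
residue conformation table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .geometry import TargetPolygon, bond_angle, place_atom, polygon_error
from .loop import (
    BOND_ANGLE,
    BOND_LENGTH,
    LatticeSpec,
    LoopSpec,
    canonical_anchor,
    instantiate_chain,
    precompute_conformations,
)
from .manifold import Manifold
from .scaffold import HotspotStub, JunctionAngle, ScaffoldGeometry, ScaffoldResidue

__all__ = [
    "PlantedFixture",
    "plant_polygon",
    "make_toy_scaffold_library",
    "make_closable_loop",
]


@dataclass(frozen=True)
class PlantedFixture:
    """n decoy clouds, each hiding one perturbed vertex of the target polygon."""

    manifolds: tuple
    planted: np.ndarray     # the true point n-tuple, (n, 3)
    polygon: TargetPolygon
    noise: float
    seed: int

    def __post_init__(self):
        err = polygon_error(self.planted, self.polygon)
        # each vertex moves by at most noise/2, so the pairwise error stays
        # within the declared noise budget
        if err > self.noise + 1e-9:
            raise ParameterError("planted tuple violates its own noise bound")


def _uniform_in_ball(rng, radius: float) -> np.ndarray:
    while True:
        v = rng.uniform(-1.0, 1.0, size=3)
        if np.dot(v, v) <= 1.0:
            return radius * v


def plant_polygon(
    polygon: TargetPolygon,
    N: int,
    noise: float,
    box: float = None,
    seed: int = 0,
) -> PlantedFixture:
    """Hide one perturbed copy of each polygon vertex among N-1 uniform decoys.

    Decoys are drawn uniformly in an axis-aligned box centered on the
    polygon centroid (side defaulting to 10x the polygon diameter, so the
    co-searched octrees share a root scale and pruning is exercised at
    several levels).  The planted point sits at a seeded random position in
    each cloud.
    """
    if N < 1:
        raise ParameterError("need at least one point per manifold")
    if noise < 0:
        raise ParameterError("noise must be non-negative")
    rng = np.random.default_rng(seed)
    center = polygon.vertices.mean(axis=0)
    side = box if box is not None else 10.0 * max(polygon.diameter, 1.0)
    manifolds = []
    planted = np.empty((polygon.n, 3))
    for i, vertex in enumerate(polygon.vertices):
        pts = center + rng.uniform(-side / 2.0, side / 2.0, size=(N, 3))
        true_pt = vertex + (_uniform_in_ball(rng, noise / 2.0) if noise > 0 else 0.0)
        slot = int(rng.integers(0, N))
        pts[slot] = true_pt
        planted[i] = true_pt
        manifolds.append(Manifold(points=pts, label=i))
    return PlantedFixture(
        manifolds=tuple(manifolds),
        planted=planted,
        polygon=polygon,
        noise=noise,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# toy scaffold library

_STUB_TRIANGLE = np.array(
    [
        [0.0, 0.0, 0.0],
        [5.2, 0.0, 0.0],
        [1.5384615384615385, 6.312659178298087, 0.0],
    ]
)  # Cβ triangle with realistic hotspot spacings (sides 5.2, 6.5, 7.3 Å)

_OPTIMAL_JUNCTION = np.deg2rad(110.0)
_CA_CB = 1.52
_N_CA = 1.46


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def _make_residue(name: str, cb: np.ndarray, ca_dir, rng) -> ScaffoldResidue:
    """A residue whose N-CA-CB junction angle is exactly the optimal value."""
    ca = cb + _CA_CB * _unit(ca_dir)
    u = _unit(cb - ca)
    w = _unit(np.cross(u, _unit(rng.normal(size=3))))
    e = np.cos(_OPTIMAL_JUNCTION) * u + np.sin(_OPTIMAL_JUNCTION) * w
    n_atom = ca + _N_CA * e
    # backbone C off the N-CA-CB plane so the mirror flip genuinely moves CB
    f = _unit(np.cross(u, w) + 0.3 * w)
    c_atom = ca + 1.52 * f
    return ScaffoldResidue(name=name, atoms={"N": n_atom, "CA": ca, "C": c_atom, "CB": cb})


def make_toy_scaffold_library(count: int, seed: int = 0):
    """A library of ``count`` 4-site scaffolds plus 3 matching hotspot stubs.

    Scaffold 0 is the known answer: three of its take-off atoms are an
    exact rigid copy of the stub attachment triangle with junction angles
    built at optimum, so it must survive the screen with zero shape and
    angle RMSD.  The rest are randomized decoys.  A count of 16 mirrors a
    four-residue l/d-combinatoric library.
    """
    if count < 1:
        raise ParameterError("library needs at least one scaffold")
    rng = np.random.default_rng(seed)

    stubs = []
    for i, cb in enumerate(_STUB_TRIANGLE):
        cg = cb + 1.52 * _unit([0.3, 0.4, 0.9])
        stubs.append(
            HotspotStub(
                name=f"hotspot{i + 1}",
                atoms={"CB": cb, "CG": cg},
                connect_atom="CB",
                optimal_angles=(JunctionAngle("N", "CA", _OPTIMAL_JUNCTION),),
            )
        )

    scaffolds = []
    for s in range(count):
        residues = []
        if s == 0:
            cbs = list(_STUB_TRIANGLE) + [np.array([8.0, -4.0, 3.0])]
        else:
            center = rng.uniform(-2.0, 8.0, size=3)
            cbs = [center + rng.uniform(-4.0, 4.0, size=3) for _ in range(4)]
        for r, cb in enumerate(cbs):
            residues.append(_make_residue(f"R{r + 1}", np.asarray(cb, dtype=float),
                                          rng.normal(size=3), rng))
        scaffolds.append(
            ScaffoldGeometry(
                scaffold_id=f"scaffold{s:02d}",
                residues=tuple(residues),
                takeoff_sites=tuple((r, "CB") for r in range(4)),
            )
        )
    return scaffolds, stubs


# ---------------------------------------------------------------------------
# closable loops

def _table_lookup(table):
    return {(round(c.phi, 12), round(c.psi, 12)): c.conf_id for c in table}


def make_closable_loop(
    k: int,
    seed: int = 0,
    grid_per_axis: int = 6,
    cube_length: float = 0.5,
    angle_tol: float = 0.2,
    lattice_margin: int = 6,
):
    """A loop spec with a planted closed loop that the search can recover.

    Builds a random valid k-residue chain from torsions drawn off a product
    grid, then derives the second pivot's anchor frame so that the chain
    read backwards is *also* a sequence of grid conformations.  Returns
    ``(spec, truth_atoms, table, truth_ids_side1, truth_ids_side2)``.
    """
    if k < 2:
        raise ParameterError("a loop needs at least 2 residues")
    rng = np.random.default_rng(seed)
    vals = 2.0 * np.pi * np.arange(grid_per_axis) / grid_per_axis
    table = precompute_conformations(
        (vals, vals), lattice_pitch=cube_length, angle_tol=angle_tol
    )
    lookup = _table_lookup(table)

    pivot1 = rng.uniform(-1.0, 1.0, size=3)
    takeoff1 = _unit(rng.normal(size=3))
    anchor1 = canonical_anchor(pivot1, takeoff1)
    ids = [int(rng.integers(0, len(table))) for _ in range(k)]
    truth = instantiate_chain(anchor1, ids, table)

    pivot2 = truth[-1]
    takeoff2 = _unit(truth[-2] - truth[-1])
    # anchor frame behind pivot 2, chosen so the first reverse residue's
    # torsions are themselves grid values
    rev_seed_conf = table[int(rng.integers(0, len(table)))]
    g1, g2 = rev_seed_conf.phi, rev_seed_conf.psi
    a1 = place_atom(truth[-3], truth[-2], truth[-1], BOND_LENGTH, BOND_ANGLE, g2)
    a2 = place_atom(truth[-2], truth[-1], a1, BOND_LENGTH, BOND_ANGLE, g1)
    anchor2 = np.vstack([a2, a1, pivot2])

    m1 = (k + 1) // 2
    m2 = k - m1
    ids1 = tuple(ids[:m1])
    # reverse side: seed conformation, then forward torsions swapped & reversed
    rev = [rev_seed_conf.conf_id]
    for t in range(2, m2 + 1):
        fwd = table[ids[k - t + 1]]
        rev.append(lookup[(round(fwd.psi, 12), round(fwd.phi, 12))])
    ids2 = tuple(rev)

    lo = truth.min(axis=0)
    hi = truth.max(axis=0)
    extent = float((hi - lo).max()) + 2.0 * lattice_margin * cube_length
    n_cells = int(np.ceil(extent / cube_length))
    lattice = LatticeSpec.centered((lo + hi) / 2.0, cube_length, n_cells)

    spec = LoopSpec(
        pivot1=pivot1,
        pivot2=pivot2,
        takeoff1=takeoff1,
        takeoff2=takeoff2,
        k=k,
        lattice=lattice,
        angle_tol=angle_tol,
        anchor1=anchor1,
        anchor2=anchor2,
    )
    return spec, truth, table, ids1, ids2
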