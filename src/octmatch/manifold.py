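"""Point-cloud manifolds of reachable binding-node positions.

A side chain with fixed bond lengths and angles reaches, through rotations
of its rotatable bonds, a cloud of possible positions for its terminal
functional group ("binding node").  Sweeping a dihedral grid over the
chain yields that cloud as an explicit point list with per-point dihedral
provenance.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import EmptyGridError, ParameterError, SizeMismatchError
from .geometry import ChainSpec, as_points, internal_to_cartesian

__all__ = [
    "Manifold",
    "DihedralGrid",
    "sample_manifold",
    "deduplicate",
    "read_manifold_tsv",
    "write_manifold_tsv",
    "read_manifold_json",
    "write_manifold_json",
    "load_chain_spec",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class Manifold:
    """A cloud of N candidate binding-node positions for one pattern vertex.

    ``provenance`` records, per point, the dihedral tuple that produced it
    (empty tuples for clouds supplied directly rather than sampled).
    """

    points: np.ndarray
    provenance: tuple = None
    label: int = 0

    def __post_init__(self):
        pts = as_points(self.points)
        if len(pts) < 1:
            raise SizeMismatchError("a manifold needs at least one point")
        prov = self.provenance
        if prov is None:
            prov = tuple(() for _ in range(len(pts)))
        else:
            prov = tuple(tuple(p) for p in prov)
        if len(prov) != len(pts):
            raise SizeMismatchError("provenance length must equal the point count")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "provenance", prov)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def bbox(self):
        return self.points.min(axis=0), self.points.max(axis=0)


@dataclass(frozen=True)
class DihedralGrid:
    """Per-rotatable-bond dihedral sample sets.

    ``mode`` is "uniform" for an even [0, 2pi) grid or "preferred" for an
    explicit user-supplied list of favored torsions (rotamer-like values
    such as ±60°, 180°); no rotamer library is bundled.
    """

    samples: tuple
    mode: str = "uniform"

    def __post_init__(self):
        cleaned = []
        for s in self.samples:
            arr = np.mod(np.asarray(s, dtype=float).reshape(-1), TWO_PI)
            if arr.size == 0:
                raise EmptyGridError("every rotatable bond needs at least one dihedral sample")
            cleaned.append(arr)
        object.__setattr__(self, "samples", tuple(cleaned))
        if self.mode not in ("uniform", "preferred"):
            raise ParameterError(f"unknown grid mode {self.mode!r}")

    @classmethod
    def uniform(cls, n_bonds: int, samples_per_bond: int) -> "DihedralGrid":
        if samples_per_bond < 1:
            raise EmptyGridError("need at least one sample per bond")
        vals = TWO_PI * np.arange(samples_per_bond) / samples_per_bond
        return cls(samples=tuple(vals.copy() for _ in range(n_bonds)), mode="uniform")

    @classmethod
    def preferred(cls, per_bond_values) -> "DihedralGrid":
        return cls(samples=tuple(per_bond_values), mode="preferred")

    @property
    def n_bonds(self) -> int:
        return len(self.samples)

    @property
    def size(self) -> int:
        return int(np.prod([len(s) for s in self.samples]))


def sample_manifold(spec: ChainSpec, grid: DihedralGrid, anchor, label: int = 0) -> Manifold:
    """Sweep the dihedral grid and collect the terminal-atom positions.

    The full Cartesian product of per-bond sample sets is enumerated in
    lexicographic order, so the output is a pure, bit-reproducible function
    of (spec, grid, anchor).
    """
    if grid.n_bonds != spec.n_rotatable:
        raise SizeMismatchError(
            f"grid has {grid.n_bonds} bonds but the chain has {spec.n_rotatable} rotatable bonds"
        )
    points = np.empty((grid.size, 3))
    prov = []
    for row, combo in enumerate(itertools.product(*grid.samples)):
        atoms = internal_to_cartesian(spec, np.asarray(combo), anchor)
        points[row] = atoms[-1]
        prov.append(tuple(float(c) for c in combo))
    return Manifold(points=points, provenance=tuple(prov), label=label)


def deduplicate(man: Manifold, cell: float) -> Manifold:
    """Collapse points sharing an axis-aligned grid cell of pitch ``cell``.

    Symmetric side chains produce exactly coincident binding nodes; this
    optional pass keeps the first point (in input order) per cell.
    """
    if cell <= 0:
        raise ParameterError("deduplication cell must be positive")
    keys = np.floor(man.points / cell).astype(np.int64)
    seen = {}
    keep = []
    for i, key in enumerate(map(tuple, keys)):
        if key not in seen:
            seen[key] = i
            keep.append(i)
    keep = np.asarray(keep, dtype=int)
    return Manifold(
        points=man.points[keep],
        provenance=tuple(man.provenance[i] for i in keep),
        label=man.label,
    )


# ---------------------------------------------------------------------------
# serialization

def write_manifold_tsv(man: Manifold, path) -> None:
    with open(path, "w") as fh:
        fh.write("# octmatch manifold: x\ty\tz (Å)\n")
        for p in man.points:
            fh.write(f"{p[0]:.9g}\t{p[1]:.9g}\t{p[2]:.9g}\n")


def read_manifold_tsv(path, label: int = 0) -> Manifold:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            rows.append([float(x) for x in line.split("\t")])
    return Manifold(points=np.asarray(rows), label=label)


def write_manifold_json(man: Manifold, path) -> None:
    payload = {
        "label": man.label,
        "points": man.points.tolist(),
        "provenance": [list(p) for p in man.provenance],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_manifold_json(path) -> Manifold:
    with open(path) as fh:
        payload = json.load(fh)
    return Manifold(
        points=np.asarray(payload["points"], dtype=float),
        provenance=tuple(tuple(p) for p in payload["provenance"]),
        label=int(payload.get("label", 0)),
    )


def load_chain_spec(path) -> ChainSpec:
    """Read a YAML chain spec (angles accepted in degrees, stored in radians).

    Expected keys: ``atoms`` (list of {name, length, angle, rotatable,
    dihedral?}) with lengths in Å and angles/dihedrals in degrees.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    atoms = doc["atoms"]
    names = [a["name"] for a in atoms]
    lengths = [float(a["length"]) for a in atoms]
    angles = [np.deg2rad(float(a["angle"])) for a in atoms]
    rotatable = [bool(a.get("rotatable", False)) for a in atoms]
    fixed = [np.deg2rad(float(a.get("dihedral", 180.0))) for a in atoms]
    return ChainSpec(
        atom_names=tuple(names),
        bond_lengths=np.asarray(lengths),
        bond_angles=np.asarray(angles),
        rotatable=np.asarray(rotatable),
        fixed_dihedrals=np.asarray(fixed),
    )
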