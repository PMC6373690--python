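"""PDB fragment reading/writing and library manifest loading.

Structural coordinates move through gemmi; coordinates are kept in the
input frame (no recentering on read).  PDB is the only structural format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gemmi
import numpy as np
import yaml

from .errors import PDBParseError
from .scaffold import HotspotStub, JunctionAngle, ScaffoldGeometry, ScaffoldResidue

log = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "read_pdb_fragment",
    "write_fragment_pdb",
    "write_loops_pdb",
    "load_scaffold_library",
    "load_stubs",
]


@dataclass(frozen=True)
class AtomRecord:
    """One coordinate record: names, residue identity and position in Å."""

    name: str
    res_name: str
    res_seq: int
    chain: str
    xyz: tuple
    element: str = ""


def read_pdb_fragment(path) -> list:
    """Parse ATOM/HETATM records into :class:`AtomRecord` lists.

    For atoms with alternate locations only the first altloc is kept (a
    warning is logged); insertion codes are ignored for fragment purposes.
    """
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    records = []
    seen_altloc = set()
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    key = (chain.name, res.seqid.num, atom.name)
                    if atom.altloc and atom.altloc != "\0":
                        if key in seen_altloc:
                            log.warning(
                                "%s: keeping first altloc for %s/%s/%s",
                                path, chain.name, res.seqid.num, atom.name,
                            )
                            continue
                        seen_altloc.add(key)
                    records.append(
                        AtomRecord(
                            name=atom.name,
                            res_name=res.name,
                            res_seq=res.seqid.num,
                            chain=chain.name,
                            xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                            element=atom.element.name,
                        )
                    )
        break  # fragments: first model only
    if not records:
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    return records


def _build_structure(name: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    return st


def write_fragment_pdb(records, path) -> None:
    """Write AtomRecords back out as a single-model PDB fragment."""
    st = _build_structure("fragment")
    model = gemmi.Model("1")
    chains = {}
    for rec in records:
        chain = chains.get(rec.chain)
        if chain is None:
            chain = gemmi.Chain(rec.chain or "A")
            chains[rec.chain] = chain
        res = None
        if len(chain) and chain[-1].seqid.num == rec.res_seq and chain[-1].name == rec.res_name:
            res = chain[-1]
        if res is None:
            res = gemmi.Residue()
            res.name = rec.res_name
            res.seqid = gemmi.SeqId(rec.res_seq, " ")
            chain.add_residue(res)
            res = chain[-1]
        atom = gemmi.Atom()
        atom.name = rec.name
        atom.pos = gemmi.Position(*rec.xyz)
        if rec.element:
            atom.element = gemmi.Element(rec.element)
        res.add_atom(atom)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_loops_pdb(loops, path) -> None:
    """Write closed loops as a multi-MODEL PDB trace (N-CA-C per residue).

    Consecutive residues share their junction atom in the loop model, so
    each residue's N coordinate duplicates the previous residue's C.
    """
    if not loops:
        raise PDBParseError("no loops to write")
    st = _build_structure("loops")
    for li, loop in enumerate(loops):
        atoms = np.asarray(loop.atoms if hasattr(loop, "atoms") else loop, dtype=float)
        model = gemmi.Model(str(li + 1))
        chain = gemmi.Chain("A")
        n_res = (len(atoms) - 1) // 2
        for r in range(n_res):
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(r + 1, " ")
            for aname, idx in (("N", 2 * r), ("CA", 2 * r + 1), ("C", 2 * r + 2)):
                atom = gemmi.Atom()
                atom.name = aname
                atom.pos = gemmi.Position(*atoms[idx])
                atom.element = gemmi.Element("N" if aname == "N" else "C")
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def _records_to_residues(records):
    residues = []
    current = None
    for rec in records:
        rid = (rec.chain, rec.res_seq, rec.res_name)
        if current is None or current[0] != rid:
            current = (rid, {})
            residues.append(current)
        current[1][rec.name] = np.asarray(rec.xyz, dtype=float)
    return residues


def load_scaffold_library(manifest_path) -> list:
    """Load scaffolds from a YAML manifest naming PDB files and take-off atoms.

    Manifest schema::

        scaffolds:
          - id: scaffold00
            pdb: scaffold00.pdb
            takeoff: [[0, CB], [1, CB], [2, CB], [3, CB]]
            enantiomers: [L, L, L, L]     # optional
            backbone: [N, CA, C]          # optional
    """
    from pathlib import Path

    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        doc = yaml.safe_load(fh)
    scaffolds = []
    for entry in doc["scaffolds"]:
        records = read_pdb_fragment(manifest_path.parent / entry["pdb"])
        backbone = tuple(entry.get("backbone", ("N", "CA", "C")))
        residues = tuple(
            ScaffoldResidue(name=f"{rid[2]}{rid[1]}", atoms=atoms, backbone=backbone)
            for rid, atoms in _records_to_residues(records)
        )
        scaffolds.append(
            ScaffoldGeometry(
                scaffold_id=str(entry["id"]),
                residues=residues,
                takeoff_sites=tuple((int(r), str(a)) for r, a in entry["takeoff"]),
                enantiomer_labels=tuple(entry["enantiomers"]) if "enantiomers" in entry else None,
            )
        )
    return scaffolds


def load_stubs(stub_yaml_path) -> list:
    """Load hotspot stubs from YAML + PDB fragments.

    Schema::

        stubs:
          - name: hotspot1
            pdb: stub1.pdb
            connect_atom: CB
            optimal_angles: [[N, CA, 110.0]]   # degrees
    """
    from pathlib import Path

    stub_yaml_path = Path(stub_yaml_path)
    with open(stub_yaml_path) as fh:
        doc = yaml.safe_load(fh)
    stubs = []
    for entry in doc["stubs"]:
        records = read_pdb_fragment(stub_yaml_path.parent / entry["pdb"])
        atoms = {}
        for rec in records:
            atoms.setdefault(rec.name, np.asarray(rec.xyz, dtype=float))
        angles = tuple(
            JunctionAngle(str(a), str(b), np.deg2rad(float(deg)))
            for a, b, deg in entry.get("optimal_angles", ())
        )
        stubs.append(
            HotspotStub(
                name=str(entry["name"]),
                atoms=atoms,
                connect_atom=str(entry["connect_atom"]),
                optimal_angles=angles,
            )
        )
    return stubs
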