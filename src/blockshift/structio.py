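"""Template structure handling.

Parses one chain of a PDB-format file into a light-weight residue list,
computes side-chain centers (centroid of side-chain heavy atoms; CA for
glycine), and maps structure residues onto the template sequence through a
global alignment, recording the sequence identity used by the refinement
gate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from .errors import StructureError
from .seqio import SequenceRecord, global_align, percent_identity

log = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}


@dataclass
class Residue3D:
    """One residue of a structure chain with named heavy-atom coordinates."""

    chain: str
    seq_label: str            # author residue number + insertion code
    aa: str                   # one-letter code, 'X' if non-standard
    backbone_atoms: dict[str, np.ndarray] = field(default_factory=dict)
    sidechain_atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def atoms(self) -> dict[str, np.ndarray]:
        return {**self.backbone_atoms, **self.sidechain_atoms}


@dataclass
class StructureChain:
    chain_id: str
    residues: list[Residue3D]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class TemplateStructureMap:
    """Partial, strictly increasing template_index -> structure index map."""

    mapping: dict[int, int]
    identity: float
    min_identity: float

    @property
    def passes_gate(self) -> bool:
        # strict ">": refinement only when identity exceeds the threshold
        return self.identity > self.min_identity


def read_pdb_chain(path: str | Path, chain_id: str, model: int = 1) -> StructureChain:
    """Read one chain from a PDB-format file.

    One residue per (resSeq, iCode); HETATM records are skipped except
    selenomethionine (MSE -> M).  For alternate locations the highest
    occupancy wins, ties going to the first-listed.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureError(f"no models in {path}")
    model_idx = min(model - 1, len(st) - 1)
    gmodel = st[model_idx]
    gchain = gmodel.find_chain(chain_id)
    if gchain is None:
        avail = ", ".join(ch.name for ch in gmodel) or "(none)"
        raise StructureError(
            f"chain {chain_id!r} not found in {path}; available chains: {avail}"
        )

    residues: list[Residue3D] = []
    for gres in gchain:
        name = gres.name.upper()
        if gres.het_flag == "H" and name != "MSE":
            continue
        aa = _THREE_TO_ONE.get(name, "X")
        icode = gres.seqid.icode.strip()
        res = Residue3D(
            chain=chain_id,
            seq_label=f"{gres.seqid.num}{icode}",
            aa=aa,
        )
        # altloc resolution per atom name: highest occupancy, first on ties
        best: dict[str, gemmi.Atom] = {}
        for atom in gres:
            if atom.element == gemmi.Element("H"):
                continue
            cur = best.get(atom.name)
            if cur is None or atom.occ > cur.occ:
                best[atom.name] = atom
        for aname, atom in best.items():
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)
            if not np.all(np.isfinite(pos)):
                raise StructureError(
                    f"non-finite coordinates for atom {aname} in {res.seq_label}"
                )
            if aname in BACKBONE_ATOMS:
                res.backbone_atoms[aname] = pos
            else:
                res.sidechain_atoms[aname] = pos
        if res.atoms:
            residues.append(res)
    if not residues:
        raise StructureError(f"no standard residues in chain {chain_id!r} of {path}")
    return StructureChain(chain_id, residues)


def side_chain_center(residue: Residue3D) -> np.ndarray:
    """Centroid of side-chain heavy atoms; CA for glycine/bare residues."""
    if residue.sidechain_atoms:
        pts = np.array(list(residue.sidechain_atoms.values()))
        return pts.mean(axis=0)
    if "CA" in residue.backbone_atoms:
        if residue.aa != "G":
            log.warning(
                "residue %s (%s) has no side-chain atoms; using CA",
                residue.seq_label, residue.aa,
            )
        return residue.backbone_atoms["CA"]
    raise StructureError(
        f"residue {residue.seq_label} has no side-chain atoms and no CA"
    )


def map_structure_to_template(template: SequenceRecord, chain: StructureChain,
                              min_identity: float = 0.5) -> TemplateStructureMap:
    """Align the template sequence to the chain sequence and map residues.

    Gate failure (identity not above ``min_identity``) is a reported
    condition, never an exception: downstream refinement returns its input
    unchanged when the gate flag is false.
    """
    chain_seq = SequenceRecord(f"{chain.chain_id}_structure", chain.sequence)
    aln = global_align(template, chain_seq)
    mapping = dict(aln.pairs())
    identity = percent_identity(aln)
    return TemplateStructureMap(mapping=mapping, identity=identity,
                                min_identity=min_identity)
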