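"""Typed structure model for docked protein-peptide complexes.

PDB parsing and writing are delegated to gemmi; this module converts the
parsed structure into a flat, explicitly-typed atom table with receptor /
peptide role labels, and provides the geometric primitives (Euclidean
distance, atom classification) that every downstream analysis shares.

Conventions: model 1 only; the highest-occupancy alternate location is kept
(ties broken alphabetically); waters and ions are dropped by default;
residue numbering and insertion codes are taken verbatim from the file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .chemistry import BACKBONE_ATOMS

__all__ = [
    "AtomRecord",
    "StructureModel",
    "read_pdb",
    "write_pdb",
    "euclid",
    "classify_atoms",
]

#: HETATM residue names always dropped (solvent and common monoatomic ions).
_SOLVENT_AND_IONS = frozenset(
    {"HOH", "WAT", "DOD", "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "SO4", "PO4"}
)


@dataclass(frozen=True)
class AtomRecord:
    """One atom with identity, coordinates and class flags."""

    serial: int
    name: str
    element: str
    residue: str
    chain: str
    resnum: int
    icode: str
    coord: tuple[float, float, float]
    occupancy: float = 1.0
    is_hetatm: bool = False

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_ATOMS

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def residue_id(self) -> tuple[str, int, str]:
        """(chain, resnum, insertion code) — residue identity tuple."""
        return (self.chain, self.resnum, self.icode)


@dataclass
class StructureModel:
    """A docked complex: atoms plus receptor/peptide role labels."""

    atoms: list[AtomRecord]
    peptide_chain: str
    receptor_chains: frozenset[str]

    def __post_init__(self) -> None:
        if self.peptide_chain in self.receptor_chains:
            raise ValueError(
                f"peptide chain {self.peptide_chain!r} also labelled as receptor"
            )

    def role_of(self, atom: AtomRecord) -> str:
        return "peptide" if atom.chain == self.peptide_chain else "receptor"

    @property
    def peptide_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain == self.peptide_chain]

    @property
    def receptor_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain in self.receptor_chains]

    def chain_atoms(self, chain: str) -> list[AtomRecord]:
        return [a for a in self.atoms if a.chain == chain]

    def residues(self, chain: str | None = None) -> list[tuple[str, int, str]]:
        """Ordered unique residue identity tuples, optionally per chain."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            if chain is None or a.chain == chain:
                seen.setdefault(a.residue_id)
        return list(seen)

    def swapped_roles(self) -> "StructureModel":
        """Role-transposed view (single-receptor-chain complexes only)."""
        if len(self.receptor_chains) != 1:
            raise ValueError("role swap requires exactly one receptor chain")
        (rec,) = self.receptor_chains
        return StructureModel(
            atoms=self.atoms,
            peptide_chain=rec,
            receptor_chains=frozenset({self.peptide_chain}),
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Rigid-body transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        atoms = [
            replace(a, coord=tuple((R @ np.asarray(a.coord) + t).tolist()))
            for a in self.atoms
        ]
        return StructureModel(
            atoms=atoms,
            peptide_chain=self.peptide_chain,
            receptor_chains=self.receptor_chains,
        )


def euclid(a: Sequence[float], b: Sequence[float]) -> float:
    """Euclidean distance between two points in Angstrom."""
    return math.dist(a, b)


def _select_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; occupancy tie -> alphabetically first altloc
    return min(atoms, key=lambda at: (-at.occ, at.altloc))


def read_pdb(
    path: str | Path,
    peptide_chain: str,
    keep_het: bool = False,
) -> StructureModel:
    """Parse a PDB complex into a role-labelled :class:`StructureModel`.

    ``peptide_chain`` names the ligand peptide; every other chain is
    receptor.  Waters and monoatomic ions are always dropped; other HETATM
    groups are kept only with ``keep_het``.
    """
    structure = gemmi.read_pdb(str(path))
    if len(structure) == 0:
        raise ValueError(f"{path}: no models found")
    model = structure[0]  # model 1 only

    atoms: list[AtomRecord] = []
    chains_seen: list[str] = []
    serial = 0
    for chain in model:
        if chain.name not in chains_seen:
            chains_seen.append(chain.name)
        for residue in chain:
            if residue.name in _SOLVENT_AND_IONS:
                continue
            is_het = residue.het_flag == "H"
            if is_het and not keep_het:
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name in by_name:
                atom = _select_altloc(by_name[name])
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=name,
                        element=atom.element.name.upper(),
                        residue=residue.name,
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        icode=(residue.seqid.icode or "").strip(),
                        coord=(atom.pos.x, atom.pos.y, atom.pos.z),
                        occupancy=atom.occ,
                        is_hetatm=is_het,
                    )
                )

    if peptide_chain not in chains_seen:
        raise ValueError(
            f"{path}: peptide chain {peptide_chain!r} not found; "
            f"available chains: {chains_seen}"
        )
    receptor = frozenset(c for c in chains_seen if c != peptide_chain)
    if not receptor:
        raise ValueError(f"{path}: no receptor chains besides {peptide_chain!r}")
    return StructureModel(
        atoms=atoms, peptide_chain=peptide_chain, receptor_chains=receptor
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as fixed-column PDB via gemmi."""
    structure = gemmi.Structure()
    structure.name = "pepterface"
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}
    last_res: dict[str, tuple[int, str]] = {}
    for a in model.atoms:
        chain = chains.get(a.chain)
        if chain is None:
            chain = gemmi.Chain(a.chain)
            chains[a.chain] = chain
        if last_res.get(a.chain) != (a.resnum, a.icode) or len(chain) == 0:
            res = gemmi.Residue()
            res.name = a.residue
            res.seqid = gemmi.SeqId(a.resnum, a.icode or " ")
            res.het_flag = "H" if a.is_hetatm else "A"
            chain.add_residue(res)
            last_res[a.chain] = (a.resnum, a.icode)
        res = chain[len(chain) - 1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.pos = gemmi.Position(*a.coord)
        atom.occ = a.occupancy
        res.add_atom(atom)
    for chain in chains.values():
        gmodel.add_chain(chain)
    structure.add_model(gmodel)
    structure.setup_entities()
    structure.write_pdb(str(path))


def classify_atoms(model: StructureModel) -> dict[str, dict[str, int | float]]:
    """Side-chain / backbone atom counts per role, all-atom and heavy-only.

    Reports both protonated (all-atom) and heavy-only tallies plus the
    side-chain : backbone ratio for each, since docked models may or may not
    carry explicit hydrogens.
    """
    out: dict[str, dict[str, int | float]] = {}
    for role in ("receptor", "peptide"):
        atoms = model.receptor_atoms if role == "receptor" else model.peptide_atoms
        counts = {"side_chain_all": 0, "backbone_all": 0,
                  "side_chain_heavy": 0, "backbone_heavy": 0}
        for a in atoms:
            kind = "backbone" if a.is_backbone else "side_chain"
            counts[f"{kind}_all"] += 1
            if not a.is_hydrogen:
                counts[f"{kind}_heavy"] += 1
        role_out: dict[str, int | float] = dict(counts)
        for suffix in ("all", "heavy"):
            bb = counts[f"backbone_{suffix}"]
            sc = counts[f"side_chain_{suffix}"]
            role_out[f"sc_bb_ratio_{suffix}"] = (sc / bb) if bb else float("nan")
        out[role] = role_out
    return out
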