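"""Geometric interaction detection at the protein-peptide interface.

Detectors for the five interaction classes used to characterize docked
complexes: close contacts (any receptor atom within 4.0 A of a peptide
atom), hydrophobic carbon-carbon contacts (4.0 A), hydrogen bonds
(donor-acceptor distance <= 4.0 A, D-H...A deviation from linearity
<= 40 degrees), salt bridges (opposite-charge group pairs) and parallel
pi-pi stacks.  ``profile`` aggregates all detectors into a per-complex
inventory with peptide-atom participation statistics.

All "within X" distance gates are inclusive (<= X).  Contact search uses a
k-d tree; tests hold it to exact agreement with the all-pairs rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .chemistry import (
    AROMATIC_RINGS,
    CTERM_NEGATIVE_ATOMS,
    NEGATIVE_GROUPS,
    NTERM_POSITIVE_ATOMS,
    POSITIVE_GROUPS,
    SIDECHAIN_ACCEPTORS,
    SIDECHAIN_DONORS,
)
from .config import GeometryConfig
from .structure_model import AtomRecord, StructureModel, euclid

__all__ = [
    "ContactRecord",
    "HydrogenBond",
    "SaltBridge",
    "PiPiStack",
    "InteractionProfile",
    "close_contacts",
    "hydrophobic_contacts",
    "hydrogen_bonds",
    "salt_bridges",
    "pipi_stacks",
    "profile",
]

logger = logging.getLogger(__name__)

ResidueId = tuple[str, int, str]

#: Maximum covalent D-H bond length used to find explicit donor hydrogens.
_H_BOND_COVALENT = 1.25


@dataclass(frozen=True)
class ContactRecord:
    receptor_atom: AtomRecord
    peptide_atom: AtomRecord
    distance: float
    kind: str  # "close" | "hydrophobic"


@dataclass(frozen=True)
class HydrogenBond:
    donor_atom: AtomRecord
    acceptor_atom: AtomRecord
    d_a_distance: float
    donor_side: str  # "protein" | "peptide"
    hydrogen_atom: AtomRecord | None = None
    deviation: float | None = None  # deg from linear D-H...A
    geometry_complete: bool = True  # False when judged on distance alone


@dataclass(frozen=True)
class SaltBridge:
    positive_residue: ResidueId
    positive_resname: str
    negative_residue: ResidueId
    negative_resname: str
    min_distance: float
    positive_side: str  # role holding the positive group


@dataclass(frozen=True)
class PiPiStack:
    residue_a: ResidueId
    residue_b: ResidueId
    centroid_distance: float
    plane_angle: float  # deg, folded to [0, 90]


def _coords(atoms: Sequence[AtomRecord]) -> np.ndarray:
    return np.array([a.coord for a in atoms], dtype=float).reshape(len(atoms), 3)


def _cross_role_pairs(
    rec: Sequence[AtomRecord], pep: Sequence[AtomRecord], cutoff: float
) -> list[tuple[AtomRecord, AtomRecord, float]]:
    """All (receptor, peptide) atom pairs with distance <= cutoff."""
    if not rec or not pep:
        return []
    tree = cKDTree(_coords(rec))
    hits = tree.query_ball_point(_coords(pep), r=cutoff)
    out = []
    for j, idxs in enumerate(hits):
        for i in sorted(idxs):
            d = euclid(rec[i].coord, pep[j].coord)
            out.append((rec[i], pep[j], d))
    out.sort(key=lambda t: (t[0].serial, t[1].serial))
    return out


def close_contacts(
    model: StructureModel, cutoff: float = 4.0, heavy_only: bool = False
) -> list[ContactRecord]:
    """Every receptor atom within ``cutoff`` of a peptide atom (inclusive)."""
    rec, pep = model.receptor_atoms, model.peptide_atoms
    if heavy_only:
        rec = [a for a in rec if not a.is_hydrogen]
        pep = [a for a in pep if not a.is_hydrogen]
    return [
        ContactRecord(r, p, d, "close")
        for r, p, d in _cross_role_pairs(rec, pep, cutoff)
    ]


def hydrophobic_contacts(model: StructureModel, cutoff: float = 4.0) -> list[ContactRecord]:
    """Peptide carbon within ``cutoff`` of a receptor carbon (inclusive)."""
    rec = [a for a in model.receptor_atoms if a.element == "C"]
    pep = [a for a in model.peptide_atoms if a.element == "C"]
    return [
        ContactRecord(r, p, d, "hydrophobic")
        for r, p, d in _cross_role_pairs(rec, pep, cutoff)
    ]


def _chain_termini(model: StructureModel) -> tuple[set[ResidueId], set[ResidueId]]:
    """First and last residue of each chain, in atom order."""
    first: dict[str, ResidueId] = {}
    last: dict[str, ResidueId] = {}
    for a in model.atoms:
        first.setdefault(a.chain, a.residue_id)
        last[a.chain] = a.residue_id
    return set(first.values()), set(last.values())


def _donor_atoms(model: StructureModel) -> list[AtomRecord]:
    donors = []
    for a in model.atoms:
        if a.is_hydrogen:
            continue
        if a.name == "N" and a.residue != "PRO":
            donors.append(a)
        elif a.name in SIDECHAIN_DONORS.get(a.residue, ()):  # type: ignore[arg-type]
            donors.append(a)
    return donors


def _acceptor_atoms(model: StructureModel) -> list[AtomRecord]:
    acceptors = []
    for a in model.atoms:
        if a.is_hydrogen:
            continue
        if a.name in ("O", "OXT"):
            acceptors.append(a)
        elif a.name in SIDECHAIN_ACCEPTORS.get(a.residue, ()):  # type: ignore[arg-type]
            acceptors.append(a)
    return acceptors


def _attached_hydrogens(model: StructureModel, donor: AtomRecord) -> list[AtomRecord]:
    return [
        a
        for a in model.atoms
        if a.is_hydrogen
        and a.residue_id == donor.residue_id
        and euclid(a.coord, donor.coord) <= _H_BOND_COVALENT
    ]


def _deviation_from_linear(donor, hydrogen, acceptor) -> float:
    """Deviation (deg) of the D-H...A arrangement from a straight line."""
    hd = np.asarray(donor.coord) - np.asarray(hydrogen.coord)
    ha = np.asarray(acceptor.coord) - np.asarray(hydrogen.coord)
    cosang = float(hd @ ha / (np.linalg.norm(hd) * np.linalg.norm(ha)))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return 180.0 - angle


def hydrogen_bonds(
    model: StructureModel,
    d_cutoff: float = 4.0,
    angle_cutoff: float = 40.0,
    no_hydrogen_cutoff: float = 3.5,
) -> list[HydrogenBond]:
    """Cross-role hydrogen bonds.

    A donor carrying an explicit hydrogen is accepted when the donor-acceptor
    distance is <= ``d_cutoff`` and the best D-H...A deviation from linearity
    is <= ``angle_cutoff``.  A donor with no resolved hydrogen falls back to
    a distance-only gate at the stricter ``no_hydrogen_cutoff`` and is
    flagged ``geometry_complete=False``.
    """
    donors = _donor_atoms(model)
    acceptors = _acceptor_atoms(model)
    bonds: list[HydrogenBond] = []
    for donor in donors:
        donor_role = model.role_of(donor)
        hydrogens = _attached_hydrogens(model, donor)
        for acceptor in acceptors:
            if model.role_of(acceptor) == donor_role:
                continue
            d = euclid(donor.coord, acceptor.coord)
            if d > d_cutoff:
                continue
            side = "protein" if donor_role == "receptor" else "peptide"
            if hydrogens:
                best = min(hydrogens, key=lambda h: _deviation_from_linear(donor, h, acceptor))
                dev = _deviation_from_linear(donor, best, acceptor)
                if dev <= angle_cutoff:
                    bonds.append(HydrogenBond(donor, acceptor, d, side, best, dev, True))
            elif d <= no_hydrogen_cutoff:
                bonds.append(HydrogenBond(donor, acceptor, d, side,
                                          None, None, False))
    bonds.sort(key=lambda b: (b.donor_atom.serial, b.acceptor_atom.serial))
    return bonds


def _charged_groups(model: StructureModel) -> list[tuple[ResidueId, str, str, list[AtomRecord]]]:
    """(residue_id, resname, sign, atoms) for every charged group.

    Side-chain groups per the residue tables, plus the N-terminal amine and
    C-terminal carboxylate of every chain.
    """
    nterm, cterm = _chain_termini(model)
    by_res: dict[ResidueId, list[AtomRecord]] = {}
    resname: dict[ResidueId, str] = {}
    for a in model.atoms:
        by_res.setdefault(a.residue_id, []).append(a)
        resname[a.residue_id] = a.residue
    groups = []
    for rid, atoms in by_res.items():
        name = resname[rid]
        for table, sign in ((POSITIVE_GROUPS, "+"), (NEGATIVE_GROUPS, "-")):
            wanted = table.get(name)
            if wanted:
                members = [a for a in atoms if a.name in wanted]
                if members:
                    groups.append((rid, name, sign, members))
        if rid in nterm:
            members = [a for a in atoms if a.name in NTERM_POSITIVE_ATOMS]
            if members:
                groups.append((rid, name, "+", members))
        if rid in cterm:
            members = [a for a in atoms if a.name in CTERM_NEGATIVE_ATOMS]
            if members:
                groups.append((rid, name, "-", members))
    return groups


def salt_bridges(model: StructureModel, cutoff: float = 4.0) -> list[SaltBridge]:
    """Opposite-charge cross-role group pairs at minimal distance <= cutoff."""
    peptide_chain = model.peptide_chain
    groups = _charged_groups(model)
    bridges: list[SaltBridge] = []
    seen: set[tuple] = set()
    for rid_a, name_a, sign_a, atoms_a in groups:
        for rid_b, name_b, sign_b, atoms_b in groups:
            if sign_a != "+" or sign_b != "-":
                continue
            role_a = "peptide" if rid_a[0] == peptide_chain else "receptor"
            role_b = "peptide" if rid_b[0] == peptide_chain else "receptor"
            if role_a == role_b:
                continue
            dmin = min(
                euclid(x.coord, y.coord) for x in atoms_a for y in atoms_b
            )
            if dmin <= cutoff:
                key = (rid_a, rid_b)
                if key not in seen:
                    seen.add(key)
                    bridges.append(SaltBridge(rid_a, name_a, rid_b, name_b,
                                              dmin, role_a))
    bridges.sort(key=lambda b: (b.positive_residue, b.negative_residue))
    return bridges


def _rings(model: StructureModel) -> list[tuple[ResidueId, np.ndarray, np.ndarray]]:
    """(residue_id, centroid, unit normal) for every resolved aromatic ring."""
    by_res: dict[ResidueId, dict[str, AtomRecord]] = {}
    resname: dict[ResidueId, str] = {}
    for a in model.atoms:
        by_res.setdefault(a.residue_id, {})[a.name] = a
        resname[a.residue_id] = a.residue
    rings = []
    for rid, atoms in by_res.items():
        for wanted in AROMATIC_RINGS.get(resname[rid], ()):
            members = [atoms[n] for n in wanted if n in atoms]
            if len(members) < 5:
                if any(n in atoms for n in wanted):
                    logger.warning(
                        "ring of %s %s has %d/%d atoms resolved; skipped",
                        resname[rid], rid, len(members), len(wanted),
                    )
                continue
            xyz = _coords(members)
            centroid = xyz.mean(axis=0)
            # normal = least-squares plane normal (smallest right singular vector)
            _, _, vt = np.linalg.svd(xyz - centroid)
            rings.append((rid, centroid, vt[2]))
    return rings


def pipi_stacks(
    model: StructureModel,
    centroid_cutoff: float = 5.5,
    angle_cutoff: float = 30.0,
) -> list[PiPiStack]:
    """Near-parallel cross-role aromatic ring pairs with nearby centroids."""
    peptide_chain = model.peptide_chain
    rings = _rings(model)
    stacks = []
    seen: set[tuple] = set()
    for i, (rid_a, cen_a, nrm_a) in enumerate(rings):
        for rid_b, cen_b, nrm_b in rings[i + 1 :]:
            role_a = rid_a[0] == peptide_chain
            role_b = rid_b[0] == peptide_chain
            if role_a == role_b:
                continue
            d = float(np.linalg.norm(cen_a - cen_b))
            if d > centroid_cutoff:
                continue
            cosang = abs(float(nrm_a @ nrm_b))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle <= angle_cutoff:
                key = (min(rid_a, rid_b), max(rid_a, rid_b))
                if key not in seen:
                    seen.add(key)
                    stacks.append(PiPiStack(rid_a, rid_b, d, angle))
    stacks.sort(key=lambda s: (s.residue_a, s.residue_b))
    return stacks


@dataclass
class InteractionProfile:
    """Per-complex interaction inventory and participation statistics."""

    system_id: str = ""
    n_close_contacts: int = 0
    n_hydrophobic_contacts: int = 0
    n_hydrogen_bonds: int = 0
    n_salt_bridges: int = 0
    n_pipi_stacks: int = 0
    donor_protein_fraction: float | None = None
    peptide_side_chain_atoms: int = 0
    peptide_backbone_atoms: int = 0
    contacted_side_chain_atoms: int = 0
    contacted_backbone_atoms: int = 0
    participation_side_chain: float | None = None
    participation_backbone: float | None = None
    contacts_per_side_chain_atom: float | None = None
    contacts_per_backbone_atom: float | None = None
    unique_sc_bb_ratio: float | None = None
    overall_sc_bb_ratio: float | None = None

    @property
    def has_salt_bridge(self) -> bool:
        return self.n_salt_bridges > 0

    @property
    def has_pipi(self) -> bool:
        return self.n_pipi_stacks > 0

    @property
    def interaction_category(self) -> str:
        if self.has_salt_bridge and self.has_pipi:
            return "both"
        if self.has_salt_bridge:
            return "salt_bridge_only"
        if self.has_pipi:
            return "pipi_only"
        return "neither"

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["interaction_category"] = self.interaction_category
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "InteractionProfile":
        data = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**data)


def profile(
    model: StructureModel,
    config: GeometryConfig | None = None,
    system_id: str = "",
) -> InteractionProfile:
    """Run every detector and compute the per-complex inventory."""
    cfg = config or GeometryConfig()
    contacts = close_contacts(model, cfg.close_contact_cutoff, cfg.heavy_only)
    hydroph = hydrophobic_contacts(model, cfg.hydrophobic_cutoff)
    hbonds = hydrogen_bonds(
        model, cfg.hbond_distance_cutoff, cfg.hbond_angle_cutoff,
        cfg.hbond_distance_no_hydrogen,
    )
    bridges = salt_bridges(model, cfg.salt_bridge_cutoff)
    stacks = pipi_stacks(model, cfg.pipi_centroid_cutoff, cfg.pipi_angle_cutoff)

    pep_atoms = model.peptide_atoms
    if cfg.heavy_only:
        pep_atoms = [a for a in pep_atoms if not a.is_hydrogen]
    n_sc = sum(not a.is_backbone for a in pep_atoms)
    n_bb = sum(a.is_backbone for a in pep_atoms)

    sc_contacted: set[int] = set()
    bb_contacted: set[int] = set()
    sc_contact_count = bb_contact_count = 0
    for c in contacts:
        if c.peptide_atom.is_backbone:
            bb_contacted.add(c.peptide_atom.serial)
            bb_contact_count += 1
        else:
            sc_contacted.add(c.peptide_atom.serial)
            sc_contact_count += 1

    donor_frac = None
    if hbonds:
        donor_frac = sum(b.donor_side == "protein" for b in hbonds) / len(hbonds)

    return InteractionProfile(
        system_id=system_id,
        n_close_contacts=len(contacts),
        n_hydrophobic_contacts=len(hydroph),
        n_hydrogen_bonds=len(hbonds),
        n_salt_bridges=len(bridges),
        n_pipi_stacks=len(stacks),
        donor_protein_fraction=donor_frac,
        peptide_side_chain_atoms=n_sc,
        peptide_backbone_atoms=n_bb,
        contacted_side_chain_atoms=len(sc_contacted),
        contacted_backbone_atoms=len(bb_contacted),
        participation_side_chain=(len(sc_contacted) / n_sc) if n_sc else None,
        participation_backbone=(len(bb_contacted) / n_bb) if n_bb else None,
        contacts_per_side_chain_atom=(
            sc_contact_count / len(sc_contacted) if sc_contacted else None
        ),
        contacts_per_backbone_atom=(
            bb_contact_count / len(bb_contacted) if bb_contacted else None
        ),
        unique_sc_bb_ratio=(
            len(sc_contacted) / len(bb_contacted) if bb_contacted else None
        ),
        overall_sc_bb_ratio=(n_sc / n_bb) if n_bb else None,
    )
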