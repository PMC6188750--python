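"""Synthetic inputs with known ground truth for every pipeline stage.

Three generator families:

* ``make_complex`` emits geometric scaffold "complexes" (PDB-writable
  structure models) in which each requested interaction — close contact,
  hydrophobic contact, hydrogen bond, salt bridge, pi-pi stack, inter-chain
  C-alpha interface pair — is planted analytically at exactly the requested
  distance/angle, widely separated from every other planted site, together
  with a ground-truth inventory in detector-comparable form.
* ``make_screening_table`` / ``make_pocket_shuffle`` emit binding-site
  screening tables with a known fraction of true signals (null p-values
  uniform, signal p-values Beta(0.1, 10)) and known pocket identity.
* ``make_decomposition`` / ``make_cohort`` emit MM/GBSA snapshot-energy and
  per-residue tables whose contributions sum to a known dG*, and whole
  cohorts of per-complex statistics drawn from stated distributions.

Fixtures are geometric scaffolds, not foldable proteins: residues carry
only the atoms the planted chemistry needs, plus far-away terminal cap
residues so that chain-terminus charged groups exist but interact with
nothing.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .energy_decomposition import (
    BindingEnergyResult,
    ResidueContribution,
    SnapshotEnergies,
    delta_g_bind,
    position_class,
)
from .interaction_profiler import InteractionProfile
from .screening_stats import ScreeningHit
from .structure_model import AtomRecord, StructureModel, write_pdb

__all__ = [
    "PlantedInteraction",
    "ComplexSpec",
    "make_complex",
    "write_complex",
    "make_screening_table",
    "make_pocket_shuffle",
    "make_decomposition",
    "CohortSpec",
    "make_cohort",
]

_KINDS = ("close_contact", "hydrophobic", "hbond", "salt_bridge", "pipi",
          "interface_ca")


@dataclass(frozen=True)
class PlantedInteraction:
    """One interaction to realize at exact geometry.

    ``distance`` is the defining distance of the kind (atom-atom for
    contacts/bonds/bridges, centroid-centroid for stacks, C-alpha pair for
    interface plants).  ``deviation`` is the D-H...A deviation from
    linearity for hydrogen bonds; ``plane_angle`` the inter-plane angle for
    stacks; ``donor_side`` chooses which role donates the hydrogen bond.
    """

    kind: str
    distance: float
    deviation: float = 5.0
    plane_angle: float = 0.0
    donor_side: str = "protein"

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown planted kind {self.kind!r}")
        if self.distance < 2.0:
            raise ValueError("planted distances below 2.0 A are unphysical")
        if self.kind == "hbond" and not (0 <= self.deviation < 90):
            raise ValueError("hbond deviation must lie in [0, 90)")


@dataclass(frozen=True)
class ComplexSpec:
    seed: int = 0
    planted: tuple[PlantedInteraction, ...] = ()
    site_spacing: float = 25.0  # A between planted sites; keeps sites independent

    def __post_init__(self) -> None:
        if self.site_spacing < 15.0:
            raise ValueError("site spacing below 15 A risks cross-site artefacts")


class _Builder:
    """Accumulates atoms chain by chain with sequential residue numbering."""

    def __init__(self) -> None:
        self.atoms_by_chain: dict[str, list[AtomRecord]] = {}
        self.next_resnum: dict[str, int] = {}

    def residue(self, chain: str, resname: str,
                atoms: Sequence[tuple[str, str, Sequence[float]]]) -> int:
        resnum = self.next_resnum.get(chain, 1)
        self.next_resnum[chain] = resnum + 1
        bucket = self.atoms_by_chain.setdefault(chain, [])
        for name, element, pos in atoms:
            bucket.append(AtomRecord(
                serial=0, name=name, element=element, residue=resname,
                chain=chain, resnum=resnum, icode="",
                coord=(float(pos[0]), float(pos[1]), float(pos[2])),
            ))
        return resnum

    def assemble(self, peptide_chain: str, receptor_chains: Iterable[str]) -> StructureModel:
        atoms: list[AtomRecord] = []
        serial = 0
        for chain in sorted(self.atoms_by_chain):
            for a in self.atoms_by_chain[chain]:
                serial += 1
                atoms.append(AtomRecord(**{**a.__dict__, "serial": serial}))
        return StructureModel(
            atoms=atoms,
            peptide_chain=peptide_chain,
            receptor_chains=frozenset(receptor_chains),
        )


def _hbond_hydrogen(d: float, deviation: float) -> np.ndarray:
    """Local position of H (1.0 A from donor at origin; acceptor at (d,0,0))
    realizing the requested D-H...A deviation from linearity."""
    if deviation == 0.0:
        return np.array([1.0, 0.0, 0.0])

    def dev_of(alpha: float) -> float:
        h = np.array([math.cos(alpha), math.sin(alpha), 0.0])
        hd = -h
        ha = np.array([d, 0.0, 0.0]) - h
        cosang = float(hd @ ha / (np.linalg.norm(hd) * np.linalg.norm(ha)))
        angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
        return 180.0 - angle

    alpha = brentq(lambda a: dev_of(a) - deviation, 1e-9, math.radians(150.0))
    return np.array([math.cos(alpha), math.sin(alpha), 0.0])


def _hexagon(center: np.ndarray, rotation: np.ndarray) -> list[np.ndarray]:
    """Benzene-ring carbon positions (radius 1.39 A) in a rotated plane."""
    pts = []
    for k in range(6):
        ang = math.radians(60.0 * k)
        local = np.array([1.39 * math.cos(ang), 1.39 * math.sin(ang), 0.0])
        pts.append(center + rotation @ local)
    return pts


def _rot_x(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([
        [1.0, 0.0, 0.0],
        [0.0, math.cos(t), -math.sin(t)],
        [0.0, math.sin(t), math.cos(t)],
    ])


_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def make_complex(spec: ComplexSpec) -> tuple[StructureModel, dict]:
    """Build the scaffold complex and its ground-truth inventory.

    The truth dictionary lists, in detector-comparable form, the hydrogen
    bonds / salt bridges / pi-pi stacks / interface pairs that the planted
    geometry makes detectable at the default cutoffs, and the exact
    all-pairs close/hydrophobic contact sets (computed by brute force over
    the emitted coordinates).
    """
    b = _Builder()
    truth: dict = {
        "hbonds": [], "salt_bridges": [], "pipi_stacks": [],
        "interface_pairs": [], "planted": [],
    }
    chains_used = {"A", "P"}

    # far-away terminal caps so every chain has termini that touch nothing
    cap_xy = {"A": -100.0, "B": -150.0, "P": -200.0}

    for i, plant in enumerate(spec.planted):
        s = np.array([spec.site_spacing * (i + 1), 0.0, 0.0])
        d = plant.distance
        if plant.kind == "close_contact":
            # proline backbone N on both sides: no donor/acceptor/carbon chemistry
            b.residue("A", "PRO", [("N", "N", s)])
            b.residue("P", "PRO", [("N", "N", s + [d, 0, 0])])
        elif plant.kind == "hydrophobic":
            b.residue("A", "ALA", [("CB", "C", s)])
            b.residue("P", "ALA", [("CB", "C", s + [d, 0, 0])])
        elif plant.kind == "hbond":
            h_local = _hbond_hydrogen(d, plant.deviation)
            donor_atoms = [("OG", "O", s), ("HG", "H", s + h_local)]
            acceptor_atoms = [("O", "O", s + [d, 0, 0])]
            if plant.donor_side == "protein":
                rn_d = b.residue("A", "SER", donor_atoms)
                rn_a = b.residue("P", "GLY", acceptor_atoms)
                donor_res, acc_res = ["A", rn_d], ["P", rn_a]
            else:
                rn_d = b.residue("P", "SER", donor_atoms)
                rn_a = b.residue("A", "GLY", acceptor_atoms)
                donor_res, acc_res = ["P", rn_d], ["A", rn_a]
            if d <= 4.0 and plant.deviation <= 40.0:
                truth["hbonds"].append({
                    "donor_residue": donor_res,
                    "acceptor_residue": acc_res,
                    "donor_side": plant.donor_side,
                })
        elif plant.kind == "salt_bridge":
            rn_pos = b.residue("A", "ARG", [("NH1", "N", s)])
            rn_neg = b.residue("P", "GLU", [("OE1", "O", s + [d, 0, 0])])
            if d <= 4.0:
                truth["salt_bridges"].append({
                    "positive_residue": ["A", rn_pos],
                    "negative_residue": ["P", rn_neg],
                })
            if d <= 3.5:
                # an unprotonated Arg NH1 against a carboxylate O also passes
                # the distance-only hydrogen-bond gate
                truth["hbonds"].append({
                    "donor_residue": ["A", rn_pos],
                    "acceptor_residue": ["P", rn_neg],
                    "donor_side": "protein",
                })
        elif plant.kind == "pipi":
            ring_a = _hexagon(s, np.eye(3))
            ring_b = _hexagon(s + [0, 0, d], _rot_x(plant.plane_angle))
            rn_a = b.residue("A", "PHE",
                             [(n, "C", p) for n, p in zip(_RING_NAMES, ring_a)])
            rn_b = b.residue("P", "PHE",
                             [(n, "C", p) for n, p in zip(_RING_NAMES, ring_b)])
            if d <= 5.5 and plant.plane_angle <= 30.0:
                truth["pipi_stacks"].append({
                    "residue_a": ["A", rn_a], "residue_b": ["P", rn_b],
                })
        elif plant.kind == "interface_ca":
            chains_used.add("B")
            rn_a = b.residue("A", "GLY", [("CA", "C", s)])
            rn_b = b.residue("B", "GLY", [("CA", "C", s + [d, 0, 0])])
            if d < 6.0:
                truth["interface_pairs"].append({
                    "residue_a": ["A", rn_a], "residue_b": ["B", rn_b],
                })
        truth["planted"].append({
            "kind": plant.kind, "distance": plant.distance,
            "deviation": plant.deviation, "plane_angle": plant.plane_angle,
            "donor_side": plant.donor_side,
        })

    for chain in sorted(chains_used):
        x = cap_xy[chain]
        for y in (-50.0, 50.0):
            b.residue(chain, "GLY", [
                ("N", "N", (x, y, 0.0)),
                ("CA", "C", (x + 1.46, y, 0.0)),
                ("C", "C", (x + 2.2, y, 1.3)),
                ("O", "O", (x + 2.2, y, 2.53)),
            ])

    model = b.assemble(peptide_chain="P",
                       receptor_chains=chains_used - {"P"})

    # brute-force all-pairs contact truth over the emitted coordinates
    rec = model.receptor_atoms
    pep = model.peptide_atoms
    rxyz = np.array([a.coord for a in rec])
    pxyz = np.array([a.coord for a in pep])
    if len(rec) and len(pep):
        dmat = np.linalg.norm(rxyz[:, None, :] - pxyz[None, :, :], axis=2)
        close = [
            [rec[i].serial, pep[j].serial, float(dmat[i, j])]
            for i, j in zip(*np.nonzero(dmat <= 4.0))
        ]
        carbon_r = np.array([a.element == "C" for a in rec])
        carbon_p = np.array([a.element == "C" for a in pep])
        hyd_mask = (dmat <= 4.0) & carbon_r[:, None] & carbon_p[None, :]
        hydrophobic = [
            [rec[i].serial, pep[j].serial, float(dmat[i, j])]
            for i, j in zip(*np.nonzero(hyd_mask))
        ]
    else:
        close, hydrophobic = [], []
    truth["close_contacts"] = sorted(close)
    truth["hydrophobic_contacts"] = sorted(hydrophobic)
    return model, truth


def write_complex(spec: ComplexSpec, outdir: str | Path) -> tuple[Path, Path]:
    """Emit complex.pdb and truth.json; byte-identical for equal specs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, truth = make_complex(spec)
    pdb_path = outdir / "complex.pdb"
    json_path = outdir / "truth.json"
    write_pdb(model, pdb_path)
    with open(json_path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return pdb_path, json_path


# ---------------------------------------------------------------------------
# screening tables

def make_screening_table(
    m0: int, m1: int, seed: int = 0, structure_id: str = "SYN1"
) -> tuple[list[ScreeningHit], np.ndarray]:
    """Screening hits with m0 true nulls and m1 true signals.

    Null p-values are Uniform(0, 1); signal p-values Beta(0.1, 10).  Returns
    the hits (shuffled) and a boolean truth array (True = signal) aligned
    with them.
    """
    if m0 < 0 or m1 < 0 or m0 + m1 < 1:
        raise ValueError("need m0, m1 >= 0 and m0 + m1 >= 1")
    rng = np.random.default_rng(seed)
    p = np.concatenate([
        rng.uniform(0.0, 1.0, size=m0),
        rng.beta(0.1, 10.0, size=m1),
    ])
    p = np.clip(p, 1e-12, 1.0)
    labels = np.concatenate([np.zeros(m0, bool), np.ones(m1, bool)])
    order = rng.permutation(m0 + m1)
    p, labels = p[order], labels[order]
    signal_pocket = frozenset(("A", r) for r in range(10, 20))
    hits = []
    for i, (pv, is_signal) in enumerate(zip(p, labels)):
        pocket = (signal_pocket if is_signal
                  else frozenset(("A", 100 + 10 * i + r) for r in range(5)))
        hits.append(ScreeningHit(
            fragment_id=f"frag{i:05d}", structure_id=structure_id, chain="A",
            p_raw=float(pv), pocket=pocket,
        ))
    return hits, labels


def make_pocket_shuffle(
    n_structures: int, p_same: float, seed: int = 0, hits_per_structure: int = 2
) -> tuple[dict[str, list[ScreeningHit]], float]:
    """Peptide-shuffle experiment: hits on many structures, each following
    hit reusing the structure's consensus pocket with probability p_same.

    Returns hits grouped by structure and the realized same-pocket fraction
    among non-representative hits (the generator's truth).
    """
    if hits_per_structure < 2:
        raise ValueError("need at least 2 hits per structure")
    rng = np.random.default_rng(seed)
    grouped: dict[str, list[ScreeningHit]] = {}
    n_follow = n_same = 0
    for s in range(n_structures):
        sid = f"STR{s:04d}"
        base = frozenset(("A", r) for r in range(1, 11))
        alt = frozenset(("A", r) for r in range(200, 210))
        hits = [ScreeningHit(fragment_id=f"{sid}_h0", structure_id=sid,
                             chain="A", p_raw=0.01, pocket=base)]
        for h in range(1, hits_per_structure):
            same = bool(rng.random() < p_same)
            n_follow += 1
            n_same += same
            hits.append(ScreeningHit(
                fragment_id=f"{sid}_h{h}", structure_id=sid, chain="A",
                p_raw=0.01, pocket=base if same else alt,
            ))
        grouped[sid] = hits
    return grouped, n_same / n_follow


# ---------------------------------------------------------------------------
# MM/GBSA tables

_PEPTIDE_TERMS = {"e_bnd": 12.0, "e_el": -45.0, "e_vdw": -8.0,
                  "g_pol": -30.0, "g_np": 3.0}
_PROTEIN_TERMS = {"e_bnd": 310.0, "e_el": -820.0, "e_vdw": -260.0,
                  "g_pol": -140.0, "g_np": 10.0}


def make_decomposition(
    dg_star: float,
    residue_contribs: Sequence[tuple[str, str, int, float]],
    noise_sd: float = 0.0,
    n_snapshots: int = 100,
    seed: int = 0,
    system_id: str = "SYN1",
    peptide_length: int | None = None,
) -> tuple[list[SnapshotEnergies], list[ResidueContribution]]:
    """Snapshot-energy and per-residue tables for a known dG*.

    ``residue_contribs`` is (chain_role, res_name, res_index, dg_contrib)
    and must sum to dG* exactly (the decomposition is exhaustive by
    construction).  Per-snapshot dG is dG* + Normal(0, noise_sd); the
    complex electrostatic term absorbs both dG* and the noise.
    """
    total = sum(c[3] for c in residue_contribs)
    if abs(total - dg_star) > 1e-9:
        raise ValueError(
            f"residue contributions sum to {total}, expected dG* = {dg_star}"
        )
    rng = np.random.default_rng(seed)
    noise = (rng.normal(0.0, noise_sd, size=n_snapshots)
             if noise_sd > 0 else np.zeros(n_snapshots))
    energies: list[SnapshotEnergies] = []
    for s in range(n_snapshots):
        energies.append(SnapshotEnergies(snapshot_index=s, role="peptide",
                                         **_PEPTIDE_TERMS))
        energies.append(SnapshotEnergies(snapshot_index=s, role="protein",
                                         **_PROTEIN_TERMS))
        complex_terms = {
            k: _PEPTIDE_TERMS[k] + _PROTEIN_TERMS[k] for k in _PEPTIDE_TERMS
        }
        complex_terms["e_el"] += dg_star + float(noise[s])
        energies.append(SnapshotEnergies(snapshot_index=s, role="complex",
                                         **complex_terms))

    if peptide_length is None:
        pep_idx = [idx for role, _, idx, _ in residue_contribs if role == "peptide"]
        peptide_length = max(pep_idx) if pep_idx else 0
    contribs = [
        ResidueContribution(
            system_id=system_id, chain_role=role, res_name=name,
            res_index=idx, dg_contrib=val,
            position_class=(position_class(idx, peptide_length)
                            if role == "peptide" else None),
        )
        for role, name, idx, val in residue_contribs
    ]
    return energies, contribs


# ---------------------------------------------------------------------------
# cohorts

@dataclass(frozen=True)
class CohortSpec:
    """Distribution parameters for a synthetic cohort of docked systems.

    Defaults emulate the characterized docking cohort: close contacts
    ~ Normal(167, 49) truncated at 0, hydrophobic contacts ~ Normal(24, 8),
    hydrogen bonds ~ Normal(4.5, 2), protein-side donor probability 0.51,
    interaction-category probabilities (bridge-only 52 %, stack-only 7.7 %,
    both 5.8 %, neither 34.6 %), conditional bridge/stack counts
    ~ Normal(1.72, 1) / Normal(1.63, 0.7) floored at 1, and binding energies
    ~ Normal(-35, 18.5) kcal/mol so that ~97 % of systems bind favourably.
    """

    n_systems: int = 104
    seed: int = 0
    contacts_mean: float = 167.0
    contacts_sd: float = 49.0
    hydrophobic_mean: float = 24.0
    hydrophobic_sd: float = 8.0
    hbond_mean: float = 4.5
    hbond_sd: float = 2.0
    donor_protein_p: float = 0.51
    category_probs: tuple[float, float, float, float] = (0.52, 0.077, 0.058, 0.346)
    bridge_mean: float = 1.72
    bridge_sd: float = 1.0
    stack_mean: float = 1.63
    stack_sd: float = 0.7
    participation_sc_mean: float = 0.238
    participation_sc_sd: float = 0.08
    participation_bb_mean: float = 0.387
    participation_bb_sd: float = 0.10
    unique_ratio_mean: float = 2.0
    unique_ratio_sd: float = 0.5
    overall_ratio_mean: float = 3.2
    overall_ratio_sd: float = 0.5
    dg_mean: float = -35.0
    dg_sd: float = 18.5
    dg_snapshot_sd: float = 5.0

    def __post_init__(self) -> None:
        if self.n_systems < 1:
            raise ValueError("cohort needs at least one system")
        # probabilities are normalized at draw time; tolerate printed-value
        # rounding (e.g. 52 + 7.7 + 5.8 + 34.6 = 100.1 %)
        if sum(self.category_probs) > 1.0 + 5e-3:
            raise ValueError("category probabilities must sum to <= 1")


def make_cohort(
    spec: CohortSpec,
) -> tuple[list[InteractionProfile], dict[str, BindingEnergyResult]]:
    """Draw a cohort of per-complex profiles and binding-energy results."""
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.category_probs, dtype=float)
    probs = probs / probs.sum()
    categories = ("salt_bridge_only", "pipi_only", "both", "neither")

    def count(mean: float, sd: float, floor: int = 0) -> int:
        return max(floor, int(round(rng.normal(mean, sd))))

    def frac(mean: float, sd: float) -> float:
        return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))

    profiles: list[InteractionProfile] = []
    energies: dict[str, BindingEnergyResult] = {}
    for i in range(spec.n_systems):
        sid = f"SYS{i:04d}"
        cat = categories[rng.choice(4, p=probs)]
        n_bridges = count(spec.bridge_mean, spec.bridge_sd, floor=1) \
            if cat in ("salt_bridge_only", "both") else 0
        n_stacks = count(spec.stack_mean, spec.stack_sd, floor=1) \
            if cat in ("pipi_only", "both") else 0
        n_hb = count(spec.hbond_mean, spec.hbond_sd, floor=1)
        n_sc = 40
        n_bb = 20
        part_sc = frac(spec.participation_sc_mean, spec.participation_sc_sd)
        part_bb = frac(spec.participation_bb_mean, spec.participation_bb_sd)
        sc_contacted = int(round(part_sc * n_sc))
        bb_contacted = int(round(part_bb * n_bb))
        profiles.append(InteractionProfile(
            system_id=sid,
            n_close_contacts=count(spec.contacts_mean, spec.contacts_sd),
            n_hydrophobic_contacts=count(spec.hydrophobic_mean, spec.hydrophobic_sd),
            n_hydrogen_bonds=n_hb,
            n_salt_bridges=n_bridges,
            n_pipi_stacks=n_stacks,
            donor_protein_fraction=float(
                rng.binomial(n_hb, spec.donor_protein_p) / n_hb
            ),
            peptide_side_chain_atoms=n_sc,
            peptide_backbone_atoms=n_bb,
            contacted_side_chain_atoms=sc_contacted,
            contacted_backbone_atoms=bb_contacted,
            participation_side_chain=sc_contacted / n_sc,
            participation_backbone=bb_contacted / n_bb,
            contacts_per_side_chain_atom=3.6,
            contacts_per_backbone_atom=2.8,
            unique_sc_bb_ratio=float(max(0.1, rng.normal(
                spec.unique_ratio_mean, spec.unique_ratio_sd))),
            overall_sc_bb_ratio=float(max(0.1, rng.normal(
                spec.overall_ratio_mean, spec.overall_ratio_sd))),
        ))
        dg = float(rng.normal(spec.dg_mean, spec.dg_sd))
        per_snap = rng.normal(dg, spec.dg_snapshot_sd, size=100)
        energies[sid] = BindingEnergyResult(
            dg_bind=float(per_snap.mean()),
            dg_sd=float(per_snap.std(ddof=1)),
            n_snapshots=100,
        )
    return profiles, energies
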