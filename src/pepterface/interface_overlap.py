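"""Inter-chain interfaces and overlap with predicted peptide pockets.

Residues on two receptor chains whose C-alpha atoms lie strictly less than
6.0 A apart define the chains' interface.  A predicted peptide pocket that
shares residues with such an interface marks a peptide that may modulate
complex formation; overlap with an annotated ligand/cofactor/catalytic site
marks a peptide that may compete with the ligand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.spatial import cKDTree

from .structure_model import StructureModel, euclid
import numpy as np

__all__ = [
    "InterfaceResidueSet",
    "SiteAnnotation",
    "interface_residues",
    "pocket_at_interface",
    "pocket_at_site",
    "read_sites_tsv",
]

logger = logging.getLogger(__name__)

ResiduePair = tuple[str, int]  # (chain, resnum)


@dataclass(frozen=True)
class InterfaceResidueSet:
    chain_pair: tuple[str, str]
    residues: frozenset[ResiduePair]
    pairs: tuple[tuple[ResiduePair, ResiduePair], ...] = ()


@dataclass(frozen=True)
class SiteAnnotation:
    structure_id: str
    site_kind: str  # "ligand" | "cofactor" | "catalytic"
    ligand_code: str  # empty permitted only for catalytic sites
    residues: frozenset[ResiduePair]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("site annotation with no residues")
        if not self.ligand_code and self.site_kind != "catalytic":
            raise ValueError("empty ligand code is only valid for catalytic sites")


def _ca_atoms(model: StructureModel, chain: str):
    atoms = [a for a in model.chain_atoms(chain) if a.name == "CA"]
    n_res = len(model.residues(chain))
    if not atoms:
        raise ValueError(f"chain {chain!r} has no C-alpha atoms")
    if len(atoms) < n_res:
        logger.warning(
            "chain %s: %d residues lack a C-alpha and are skipped",
            chain, n_res - len(atoms),
        )
    return atoms


def interface_residues(
    model: StructureModel, chain_a: str, chain_b: str, cutoff: float = 6.0
) -> InterfaceResidueSet:
    """Residues of two chains with any C-alpha pair strictly < ``cutoff``."""
    ca_a = _ca_atoms(model, chain_a)
    ca_b = _ca_atoms(model, chain_b)
    tree = cKDTree(np.array([a.coord for a in ca_b]))
    members: set[ResiduePair] = set()
    pairs: list[tuple[ResiduePair, ResiduePair]] = []
    for a in ca_a:
        for j in sorted(tree.query_ball_point(a.coord, r=cutoff)):
            b = ca_b[j]
            if euclid(a.coord, b.coord) < cutoff:  # strict, per the 6.0 A rule
                ra = (a.chain, a.resnum)
                rb = (b.chain, b.resnum)
                members.update((ra, rb))
                pairs.append((ra, rb))
    return InterfaceResidueSet(
        chain_pair=(chain_a, chain_b),
        residues=frozenset(members),
        pairs=tuple(sorted(pairs)),
    )


def pocket_at_interface(
    pocket: Iterable[ResiduePair],
    iface: InterfaceResidueSet,
    min_shared: int = 1,
) -> tuple[bool, frozenset[ResiduePair]]:
    """Does the predicted pocket touch the inter-chain interface?"""
    shared = frozenset(pocket) & iface.residues
    return len(shared) >= min_shared, frozenset(shared)


def pocket_at_site(
    pocket: Iterable[ResiduePair],
    site: SiteAnnotation,
    min_shared: int = 1,
) -> tuple[bool, frozenset[ResiduePair], str]:
    """Does the predicted pocket overlap an annotated functional site?"""
    shared = frozenset(pocket) & site.residues
    return len(shared) >= min_shared, frozenset(shared), site.site_kind


def _parse_residues(token: str) -> frozenset[ResiduePair]:
    out = set()
    for item in str(token).split(";"):
        item = item.strip()
        if item:
            chain, _, resnum = item.partition(":")
            out.add((chain, int(resnum)))
    return frozenset(out)


def read_sites_tsv(path: str | Path) -> list[SiteAnnotation]:
    """Site annotations: structure_id, site_kind, ligand_code, residues.

    ``residues`` is semicolon-joined chain:resnum tokens; an empty ligand
    code marks a catalytic-only site.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [
        SiteAnnotation(
            structure_id=row.structure_id,
            site_kind=row.site_kind,
            ligand_code=row.ligand_code,
            residues=_parse_residues(row.residues),
        )
        for row in df.itertuples(index=False)
    ]
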