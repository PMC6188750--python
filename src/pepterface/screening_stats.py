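"""Multiple-testing statistics over binding-site screening output.

The binding-site screen produces one raw p-value per peptide x structure
pair plus a predicted pocket (set of protein residues).  This module applies
Benjamini-Hochberg step-up adjustment, filters at an FDR cutoff (the screen
uses a deliberately permissive 0.25), and measures pocket consistency among
peptides predicted to bind the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ScreeningHit",
    "bh_adjust",
    "filter_fdr",
    "pocket_consistency",
    "read_hits_tsv",
    "write_hits_tsv",
    "adjust_hits",
]

ResidueId = tuple[str, int]


@dataclass
class ScreeningHit:
    """One peptide x structure binding-site prediction."""

    fragment_id: str
    structure_id: str
    chain: str
    p_raw: float
    pocket: frozenset[ResidueId]
    p_adj: float | None = None
    retained: bool | None = None


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Standard step-up rule: sort ascending, scale p_(i) by m/i, enforce
    monotonicity by a cumulative minimum from the largest rank down, cap at
    1, and restore input order.  Ties are safe by construction.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_hits(hits: Iterable[ScreeningHit]) -> list[ScreeningHit]:
    """Populate ``p_adj`` on a collection of hits (jointly adjusted)."""
    hits = list(hits)
    if not hits:
        return hits
    adjusted = bh_adjust([h.p_raw for h in hits])
    return [replace(h, p_adj=float(q)) for h, q in zip(hits, adjusted)]


def filter_fdr(hits: Iterable[ScreeningHit], cutoff: float = 0.25) -> list[ScreeningHit]:
    """Hits whose adjusted p-value is <= cutoff, input order preserved."""
    out = []
    for h in hits:
        if h.p_adj is None:
            raise ValueError(f"hit {h.fragment_id}x{h.structure_id} has no p_adj")
        if h.p_adj <= cutoff:
            out.append(h)
    return out


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def pocket_consistency(
    hits_on_structure: Sequence[ScreeningHit], jaccard_min: float = 0.5
) -> dict[str, int]:
    """Do peptides hitting one structure share a binding pocket?

    Pockets are clustered greedily against first-seen representatives at a
    residue-set Jaccard similarity >= ``jaccard_min``; the largest cluster
    defines the consensus pocket.  Returns counts of hits in ("same") and
    outside ("different") the consensus cluster; the two counts partition
    the input.
    """
    if len(hits_on_structure) < 2:
        raise ValueError("pocket consistency needs at least 2 hits on a structure")
    structures = {h.structure_id for h in hits_on_structure}
    if len(structures) != 1:
        raise ValueError(f"hits span multiple structures: {sorted(structures)}")

    representatives: list[frozenset[ResidueId]] = []
    assignment: list[int] = []
    for h in hits_on_structure:
        for ci, rep in enumerate(representatives):
            if _jaccard(h.pocket, rep) >= jaccard_min:
                assignment.append(ci)
                break
        else:
            representatives.append(h.pocket)
            assignment.append(len(representatives) - 1)
    counts = np.bincount(assignment, minlength=len(representatives))
    n_same = int(counts.max())
    return {
        "n_same_pocket": n_same,
        "n_different_pocket": len(hits_on_structure) - n_same,
    }


# ---------------------------------------------------------------------------
# TSV interface: fragment_id, structure_id, chain, p_raw, pocket
# (pocket as semicolon-joined chain:resnum tokens)

def _parse_pocket(token: str) -> frozenset[ResidueId]:
    if not token or pd.isna(token):
        return frozenset()
    out = set()
    for item in str(token).split(";"):
        chain, _, resnum = item.strip().partition(":")
        out.add((chain, int(resnum)))
    return frozenset(out)


def _format_pocket(pocket: frozenset[ResidueId]) -> str:
    return ";".join(f"{c}:{r}" for c, r in sorted(pocket))


def read_hits_tsv(path: str | Path) -> list[ScreeningHit]:
    df = pd.read_csv(path, sep="\t", dtype={"fragment_id": str, "structure_id": str})
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            ScreeningHit(
                fragment_id=row.fragment_id,
                structure_id=row.structure_id,
                chain=str(row.chain),
                p_raw=float(row.p_raw),
                pocket=_parse_pocket(getattr(row, "pocket", "")),
                p_adj=float(row.p_adj) if hasattr(row, "p_adj") else None,
            )
        )
    return hits


def write_hits_tsv(hits: Iterable[ScreeningHit], path: str | Path) -> None:
    rows = [
        {
            "fragment_id": h.fragment_id,
            "structure_id": h.structure_id,
            "chain": h.chain,
            "p_raw": h.p_raw,
            "p_adj": h.p_adj,
            "retained": h.retained,
            "pocket": _format_pocket(h.pocket),
        }
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
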