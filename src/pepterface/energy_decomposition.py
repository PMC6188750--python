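"""MM/GBSA binding-energy aggregation and per-residue contribution analysis.

The end-point binding free energy is the snapshot average

    dG_bind = < G_complex - G_protein - G_peptide >

with each Gibbs term the sum G = E_bnd + E_el + E_vdw + G_pol + G_np - TS;
the entropy term TS is omitted in the default workflow.  Per-snapshot terms
arrive as tables produced by an MM/GBSA engine; no simulation or solvation
solver runs here.

The per-residue analysis finds, per system, the residue with the largest
absolute contribution, sets the prominence threshold at a fraction (default
40 %) of that value, and summarizes selected residues by amino-acid type,
chain role and position within the peptide.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SnapshotEnergies",
    "BindingEnergyResult",
    "ResidueContribution",
    "gibbs_sum",
    "delta_g_bind",
    "select_prominent",
    "position_class",
    "contribution_summary",
    "read_energies_tsv",
    "read_contributions_tsv",
]

ROLES = ("complex", "protein", "peptide")


@dataclass(frozen=True)
class SnapshotEnergies:
    """One MM/GBSA term set for one snapshot of one role (kcal/mol)."""

    snapshot_index: int
    role: str  # "complex" | "protein" | "peptide"
    e_bnd: float
    e_el: float
    e_vdw: float
    g_pol: float
    g_np: float
    ts: float | None = None  # entropy term, absent in the default workflow

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


@dataclass(frozen=True)
class BindingEnergyResult:
    dg_bind: float  # kcal/mol, mean over snapshots
    dg_sd: float    # kcal/mol, sample SD (n-1); 0 for a single snapshot
    n_snapshots: int


@dataclass(frozen=True)
class ResidueContribution:
    system_id: str
    chain_role: str  # "protein" | "peptide"
    res_name: str
    res_index: int
    dg_contrib: float
    position_class: str | None = None  # peptide residues only

    def __post_init__(self) -> None:
        if self.chain_role not in ("protein", "peptide"):
            raise ValueError(f"unknown chain role {self.chain_role!r}")
        if (self.position_class is not None) != (self.chain_role == "peptide"):
            raise ValueError("position_class is defined iff chain_role == peptide")


def gibbs_sum(snapshot: SnapshotEnergies) -> float:
    """G = E_bnd + E_el + E_vdw + G_pol + G_np - TS (TS -> 0 when absent)."""
    terms = [snapshot.e_bnd, snapshot.e_el, snapshot.e_vdw,
             snapshot.g_pol, snapshot.g_np]
    if snapshot.ts is not None:
        terms.append(-snapshot.ts)
    if not all(math.isfinite(t) for t in terms):
        raise ValueError(
            f"non-finite energy term in snapshot {snapshot.snapshot_index} "
            f"({snapshot.role})"
        )
    return float(sum(terms))


def delta_g_bind(snapshots: Iterable[SnapshotEnergies]) -> BindingEnergyResult:
    """Snapshot-averaged binding energy from complex/protein/peptide terms.

    Every snapshot index must provide all three roles; per-snapshot
    dG = G_complex - G_protein - G_peptide, averaged arithmetically with the
    sample standard deviation (n-1) alongside.
    """
    by_index: dict[int, dict[str, SnapshotEnergies]] = {}
    for snap in snapshots:
        slot = by_index.setdefault(snap.snapshot_index, {})
        if snap.role in slot:
            raise ValueError(
                f"duplicate role {snap.role!r} for snapshot {snap.snapshot_index}"
            )
        slot[snap.role] = snap
    if not by_index:
        raise ValueError("no snapshots supplied")
    deltas = []
    for idx in sorted(by_index):
        slot = by_index[idx]
        missing = [r for r in ROLES if r not in slot]
        if missing:
            raise ValueError(f"snapshot {idx} is missing roles {missing}")
        deltas.append(
            gibbs_sum(slot["complex"])
            - gibbs_sum(slot["protein"])
            - gibbs_sum(slot["peptide"])
        )
    arr = np.asarray(deltas)
    if arr.size == 1:
        warnings.warn("single snapshot: dg_sd reported as 0", stacklevel=2)
        sd = 0.0
    else:
        sd = float(arr.std(ddof=1))
    return BindingEnergyResult(
        dg_bind=float(arr.mean()), dg_sd=sd, n_snapshots=int(arr.size)
    )


def select_prominent(
    contribs: Sequence[ResidueContribution], fraction: float = 0.4
) -> list[ResidueContribution]:
    """Residues contributing at least ``fraction`` of the extreme value.

    The extreme is the largest absolute contribution in the system,
    stabilizing or destabilizing; selection is |dg_contrib| >= fraction * M
    (inclusive).  An all-zero system selects nothing, with a warning.
    """
    if not contribs:
        raise ValueError("no residue contributions supplied")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    m = max(abs(c.dg_contrib) for c in contribs)
    if m == 0.0:
        warnings.warn("all contributions are zero; nothing selected", stacklevel=2)
        return []
    threshold = fraction * m
    return [c for c in contribs if abs(c.dg_contrib) >= threshold]


def position_class(residue_index: int, peptide_length: int) -> str:
    """N-terminal / C-terminal / internal from a 1-based residue index."""
    if not (1 <= residue_index <= peptide_length):
        raise ValueError(
            f"residue index {residue_index} outside 1..{peptide_length}"
        )
    if residue_index == 1:
        return "N-terminal"
    if residue_index == peptide_length:
        return "C-terminal"
    return "internal"


def contribution_summary(
    selected: Iterable[ResidueContribution],
) -> dict[str, pd.DataFrame]:
    """Appearance counts and mean contributions of selected residues.

    Returns two tables: ``by_type`` keyed by (chain_role, res_name) and
    ``by_position`` keyed by (res_name, position_class) over peptide
    residues only.
    """
    rows = [
        {
            "system_id": c.system_id,
            "chain_role": c.chain_role,
            "res_name": c.res_name,
            "position_class": c.position_class,
            "dg_contrib": c.dg_contrib,
        }
        for c in selected
    ]
    if not rows:
        raise ValueError("no selected residues to summarize")
    df = pd.DataFrame(rows)
    by_type = (
        df.groupby(["chain_role", "res_name"])["dg_contrib"]
        .agg(count="count", mean_dg="mean")
        .reset_index()
    )
    pep = df[df.chain_role == "peptide"]
    if len(pep):
        by_position = (
            pep.groupby(["res_name", "position_class"])["dg_contrib"]
            .agg(count="count", mean_dg="mean")
            .reset_index()
        )
    else:
        by_position = pd.DataFrame(
            columns=["res_name", "position_class", "count", "mean_dg"]
        )
    return {"by_type": by_type, "by_position": by_position}


# ---------------------------------------------------------------------------
# TSV interfaces

def read_energies_tsv(path: str | Path) -> dict[str, list[SnapshotEnergies]]:
    """Snapshot energy tables keyed by system_id.

    Columns: system_id, snapshot, role, e_bnd, e_el, e_vdw, g_pol, g_np
    and optionally ts.
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[SnapshotEnergies]] = {}
    has_ts = "ts" in df.columns
    for row in df.itertuples(index=False):
        ts = getattr(row, "ts", None) if has_ts else None
        if ts is not None and (isinstance(ts, float) and math.isnan(ts)):
            ts = None
        out.setdefault(str(row.system_id), []).append(
            SnapshotEnergies(
                snapshot_index=int(row.snapshot),
                role=str(row.role),
                e_bnd=float(row.e_bnd),
                e_el=float(row.e_el),
                e_vdw=float(row.e_vdw),
                g_pol=float(row.g_pol),
                g_np=float(row.g_np),
                ts=None if ts is None else float(ts),
            )
        )
    return out


def read_contributions_tsv(path: str | Path) -> dict[str, list[ResidueContribution]]:
    """Per-residue decomposition tables keyed by system_id.

    Columns: system_id, chain_role, res_name, res_index, dg_contrib and,
    for peptide residues, peptide_length (to derive the position class).
    """
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[ResidueContribution]] = {}
    for row in df.itertuples(index=False):
        role = str(row.chain_role)
        pclass = None
        if role == "peptide":
            pclass = position_class(int(row.res_index), int(row.peptide_length))
        out.setdefault(str(row.system_id), []).append(
            ResidueContribution(
                system_id=str(row.system_id),
                chain_role=role,
                res_name=str(row.res_name),
                res_index=int(row.res_index),
                dg_contrib=float(row.dg_contrib),
                position_class=pclass,
            )
        )
    return out
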