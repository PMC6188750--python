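"""Dataset-level statistics across many docked protein-peptide complexes.

Aggregates per-complex interaction profiles (and optionally binding-energy
results) into the cohort summary: mean +/- SD interaction counts, the
salt-bridge / pi-pi category partition with conditional means, peptide-atom
participation averages and the fraction of systems with favourable
(negative) binding energy.  The "+/-" throughout is the sample standard
deviation (n-1).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .energy_decomposition import BindingEnergyResult
from .interaction_profiler import InteractionProfile

__all__ = ["DatasetSummary", "aggregate", "summary_table"]

_CATEGORIES = ("salt_bridge_only", "pipi_only", "both", "neither")


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def _mean_of(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


@dataclass
class DatasetSummary:
    n_systems: int
    mean_close_contacts: float
    sd_close_contacts: float
    mean_hydrophobic_contacts: float
    sd_hydrophobic_contacts: float
    mean_hydrogen_bonds: float
    sd_hydrogen_bonds: float
    donor_protein_fraction: float | None
    category_fractions: dict[str, float]
    conditional_mean_salt_bridges: float | None
    conditional_sd_salt_bridges: float | None
    conditional_mean_pipi_stacks: float | None
    conditional_sd_pipi_stacks: float | None
    mean_participation_side_chain: float | None
    mean_participation_backbone: float | None
    mean_contacts_per_side_chain_atom: float | None
    mean_contacts_per_backbone_atom: float | None
    mean_unique_sc_bb_ratio: float | None
    mean_overall_sc_bb_ratio: float | None
    n_energy_systems: int = 0
    fraction_negative_dg: float | None = None
    mean_dg_bind: float | None = None
    sd_dg_bind: float | None = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def aggregate(
    profiles: Sequence[InteractionProfile],
    energies: Mapping[str, BindingEnergyResult] | Sequence[BindingEnergyResult] | None = None,
) -> DatasetSummary:
    """Cohort summary over per-complex profiles (order-independent)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to aggregate")

    mean_cc, sd_cc = _mean_sd([p.n_close_contacts for p in profiles])
    mean_hp, sd_hp = _mean_sd([p.n_hydrophobic_contacts for p in profiles])
    mean_hb, sd_hb = _mean_sd([p.n_hydrogen_bonds for p in profiles])

    n = len(profiles)
    cats = [p.interaction_category for p in profiles]
    category_fractions = {c: cats.count(c) / n for c in _CATEGORIES}

    bridge_counts = [p.n_salt_bridges for p in profiles if p.has_salt_bridge]
    stack_counts = [p.n_pipi_stacks for p in profiles if p.has_pipi]
    cm_sb = csd_sb = cm_pp = csd_pp = None
    if bridge_counts:
        cm_sb, csd_sb = _mean_sd(bridge_counts)
    if stack_counts:
        cm_pp, csd_pp = _mean_sd(stack_counts)

    donor_fracs = [p.donor_protein_fraction for p in profiles
                   if p.donor_protein_fraction is not None]

    dg_values: list[float] = []
    if energies is not None:
        results = (
            list(energies.values()) if isinstance(energies, Mapping) else list(energies)
        )
        dg_values = [r.dg_bind for r in results]

    return DatasetSummary(
        n_systems=n,
        mean_close_contacts=mean_cc,
        sd_close_contacts=sd_cc,
        mean_hydrophobic_contacts=mean_hp,
        sd_hydrophobic_contacts=sd_hp,
        mean_hydrogen_bonds=mean_hb,
        sd_hydrogen_bonds=sd_hb,
        donor_protein_fraction=_mean_of(donor_fracs),
        category_fractions=category_fractions,
        conditional_mean_salt_bridges=cm_sb,
        conditional_sd_salt_bridges=csd_sb,
        conditional_mean_pipi_stacks=cm_pp,
        conditional_sd_pipi_stacks=csd_pp,
        mean_participation_side_chain=_mean_of(
            [p.participation_side_chain for p in profiles
             if p.participation_side_chain is not None]
        ),
        mean_participation_backbone=_mean_of(
            [p.participation_backbone for p in profiles
             if p.participation_backbone is not None]
        ),
        mean_contacts_per_side_chain_atom=_mean_of(
            [p.contacts_per_side_chain_atom for p in profiles
             if p.contacts_per_side_chain_atom is not None]
        ),
        mean_contacts_per_backbone_atom=_mean_of(
            [p.contacts_per_backbone_atom for p in profiles
             if p.contacts_per_backbone_atom is not None]
        ),
        mean_unique_sc_bb_ratio=_mean_of(
            [p.unique_sc_bb_ratio for p in profiles
             if p.unique_sc_bb_ratio is not None]
        ),
        mean_overall_sc_bb_ratio=_mean_of(
            [p.overall_sc_bb_ratio for p in profiles
             if p.overall_sc_bb_ratio is not None]
        ),
        n_energy_systems=len(dg_values),
        fraction_negative_dg=(
            sum(v < 0 for v in dg_values) / len(dg_values) if dg_values else None
        ),
        mean_dg_bind=_mean_of(dg_values),
        sd_dg_bind=(_mean_sd(dg_values)[1] if len(dg_values) > 1 else None),
    )


def summary_table(summary: DatasetSummary) -> pd.DataFrame:
    """Human-readable two-column table of the dataset summary."""
    rows: list[tuple[str, str]] = [
        ("systems", str(summary.n_systems)),
        ("close contacts (mean±sd)",
         f"{summary.mean_close_contacts:.1f}±{summary.sd_close_contacts:.1f}"),
        ("hydrophobic contacts (mean±sd)",
         f"{summary.mean_hydrophobic_contacts:.1f}±{summary.sd_hydrophobic_contacts:.1f}"),
        ("hydrogen bonds (mean±sd)",
         f"{summary.mean_hydrogen_bonds:.1f}±{summary.sd_hydrogen_bonds:.1f}"),
    ]
    if summary.donor_protein_fraction is not None:
        rows.append(("protein-side H-bond donors",
                     f"{100 * summary.donor_protein_fraction:.1f}%"))
    for cat in _CATEGORIES:
        rows.append((f"systems with {cat.replace('_', ' ')}",
                     f"{100 * summary.category_fractions[cat]:.1f}%"))
    if summary.conditional_mean_salt_bridges is not None:
        rows.append(("salt bridges per bridged system",
                     f"{summary.conditional_mean_salt_bridges:.2f}"))
    if summary.conditional_mean_pipi_stacks is not None:
        rows.append(("pi-pi stacks per stacking system",
                     f"{summary.conditional_mean_pipi_stacks:.2f}"))
    if summary.fraction_negative_dg is not None:
        rows.append(("systems with negative dG_bind",
                     f"{100 * summary.fraction_negative_dg:.1f}%"))
    return pd.DataFrame(rows, columns=["statistic", "value"])
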