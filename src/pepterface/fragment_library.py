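"""Sliding-window k-mer fragment library and hydropathy descriptors.

Stress-induced peptides (SIPs) arrive as pre-translated amino-acid
sequences; this module cuts them into overlapping k-mers (the docking
screen's query library) and computes per-fragment Kyte-Doolittle hydropathy
(GRAVY) and composition descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .chemistry import AROMATIC_AA, CHARGED_AA, KYTE_DOOLITTLE, STANDARD_AA

__all__ = [
    "SIPRecord",
    "PeptideFragment",
    "HydropathyResult",
    "read_fasta",
    "generate_fragments",
    "generate_library",
    "gravy",
    "library_summary",
    "fragments_to_table",
]


class SequenceError(ValueError):
    """Raised for empty sequences or non-standard residue letters."""


def _validate_sequence(seq: str, source: str = "sequence") -> str:
    seq = seq.upper()
    if not seq:
        raise SequenceError(f"{source} is empty")
    for i, letter in enumerate(seq):
        if letter not in STANDARD_AA:
            raise SequenceError(
                f"{source} contains non-standard residue {letter!r} at position {i}"
            )
    return seq


@dataclass(frozen=True)
class SIPRecord:
    """A stress-induced peptide: identifier plus validated sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _validate_sequence(self.sequence, f"SIP {self.id!r}")
        )


@dataclass(frozen=True)
class PeptideFragment:
    """A k-mer with provenance: parent SIP id, 0-based offset and length.

    Coordinates are half-open: ``sequence == parent[start : start + k]``.
    """

    parent_id: str
    start: int
    k: int
    sequence: str

    def __post_init__(self) -> None:
        if not (len(self.sequence) == self.k):
            raise ValueError("fragment sequence length disagrees with k")


@dataclass(frozen=True)
class HydropathyResult:
    """GRAVY score with hydropathy class and composition counts."""

    gravy: float
    klass: str  # "hydrophobic" (gravy > 0) or "hydrophilic"
    n_charged: int
    n_aromatic: int


def read_fasta(path: str | Path) -> list[SIPRecord]:
    """Read a multi-record FASTA of SIP sequences, validating residues."""
    records = [
        SIPRecord(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def generate_fragments(
    sip: SIPRecord, kmin: int = 4, kmax: int = 10
) -> list[PeptideFragment]:
    """All sliding-window k-mers of ``sip`` for k in [kmin, kmax], step 1.

    Fragments are ordered by (k, start); duplicates by sequence are retained
    with distinct provenance.  For each k the number of windows is
    max(0, L - k + 1).
    """
    if not (1 <= kmin <= kmax):
        raise ValueError(f"require 1 <= kmin <= kmax, got kmin={kmin} kmax={kmax}")
    seq = sip.sequence
    out: list[PeptideFragment] = []
    for k in range(kmin, kmax + 1):
        for start in range(0, len(seq) - k + 1):
            out.append(
                PeptideFragment(
                    parent_id=sip.id, start=start, k=k, sequence=seq[start : start + k]
                )
            )
    return out


def generate_library(
    sips: Iterable[SIPRecord],
    kmin: int = 4,
    kmax: int = 10,
    dedup: bool = False,
) -> list[PeptideFragment]:
    """Fragment library over many SIPs; ``dedup`` collapses by sequence.

    Deduplication keeps the first-seen fragment of each distinct sequence
    (scan order: SIP input order, then (k, start)).
    """
    library: list[PeptideFragment] = []
    for sip in sips:
        library.extend(generate_fragments(sip, kmin, kmax))
    if dedup:
        seen: set[str] = set()
        unique = []
        for frag in library:
            if frag.sequence not in seen:
                seen.add(frag.sequence)
                unique.append(frag)
        library = unique
    return library


def gravy(sequence: str) -> HydropathyResult:
    """Grand average of hydropathy (mean Kyte-Doolittle value per residue).

    The hydrophobic class is strictly positive GRAVY; a score of exactly 0
    classes as hydrophilic.  Charged counts cover {R, K, H, D, E}; aromatic
    counts cover {H, F, Y, W} — histidine belongs to both sets.
    """
    seq = _validate_sequence(sequence)
    score = sum(KYTE_DOOLITTLE[a] for a in seq) / len(seq)
    return HydropathyResult(
        gravy=score,
        klass="hydrophobic" if score > 0 else "hydrophilic",
        n_charged=sum(a in CHARGED_AA for a in seq),
        n_aromatic=sum(a in AROMATIC_AA for a in seq),
    )


def library_summary(fragments: Iterable[PeptideFragment]) -> dict[str, float]:
    """Dataset-level hydropathy-class and residue-composition fractions.

    Returns fractions of hydrophilic/hydrophobic fragments (summing to 1)
    and residue-level charged and aromatic fractions pooled over all
    fragment residues.
    """
    fragments = list(fragments)
    if not fragments:
        raise ValueError("cannot summarise an empty fragment collection")
    n_hydrophobic = 0
    n_charged = n_aromatic = n_residues = 0
    for frag in fragments:
        result = gravy(frag.sequence)
        n_hydrophobic += result.klass == "hydrophobic"
        n_charged += result.n_charged
        n_aromatic += result.n_aromatic
        n_residues += len(frag.sequence)
    n = len(fragments)
    return {
        "n_fragments": n,
        "frac_hydrophobic": n_hydrophobic / n,
        "frac_hydrophilic": (n - n_hydrophobic) / n,
        "frac_charged_residues": n_charged / n_residues,
        "frac_aromatic_residues": n_aromatic / n_residues,
    }


def fragments_to_table(fragments: Iterable[PeptideFragment]) -> pd.DataFrame:
    """Flat table of fragments with hydropathy descriptors (TSV-ready)."""
    rows = []
    for frag in fragments:
        h = gravy(frag.sequence)
        rows.append(
            {
                "parent_id": frag.parent_id,
                "start": frag.start,
                "k": frag.k,
                "sequence": frag.sequence,
                "gravy": round(h.gravy, 6),
                "klass": h.klass,
                "n_charged": h.n_charged,
                "n_aromatic": h.n_aromatic,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "parent_id", "start", "k", "sequence",
            "gravy", "klass", "n_charged", "n_aromatic",
        ],
    )


def _iter_windows(seq: str, kmin: int, kmax: int) -> Iterator[tuple[int, int]]:
    # brute-force window enumeration, kept for symmetry with tests
    for k in range(kmin, kmax + 1):
        for start in range(len(seq) - k + 1):
            yield k, start
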