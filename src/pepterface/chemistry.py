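"""Residue-level chemistry tables used across the package.

All tables are keyed by standard three- or one-letter residue codes.  They
are deliberately stored as plain module constants so that every cutoff and
atom-class decision is inspectable and versioned with the code.
"""

from __future__ import annotations

#: Kyte & Doolittle (1982) hydropathy scale, one value per standard residue.
#: Positive = hydrophobic.  Range of the scale itself is [-4.5, 4.5].
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

STANDARD_AA: frozenset[str] = frozenset(KYTE_DOOLITTLE)

#: Charged residues for composition statistics (His counted as charged).
CHARGED_AA: frozenset[str] = frozenset("RKHDE")

#: Aromatic residues for composition statistics (His counted as aromatic too).
AROMATIC_AA: frozenset[str] = frozenset("HFYW")

ONE_TO_THREE: dict[str, str] = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE: dict[str, str] = {v: k for k, v in ONE_TO_THREE.items()}

#: Backbone atom names; OXT and amide/N-terminal hydrogens class as backbone.
BACKBONE_ATOMS: frozenset[str] = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)

#: Heavy-atom hydrogen-bond donors per residue (atom carries at least one
#: polar hydrogen in the standard protonation state).  Backbone N is a donor
#: for every residue except proline.
SIDECHAIN_DONORS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "ASN": frozenset({"ND2"}),
    "GLN": frozenset({"NE2"}),
    "TRP": frozenset({"NE1"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "CYS": frozenset({"SG"}),
}

#: Heavy-atom hydrogen-bond acceptors per residue; backbone O/OXT accept for
#: every residue.
SIDECHAIN_ACCEPTORS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
    "ASN": frozenset({"OD1"}),
    "GLN": frozenset({"OE1"}),
    "HIS": frozenset({"ND1", "NE2"}),
    "SER": frozenset({"OG"}),
    "THR": frozenset({"OG1"}),
    "TYR": frozenset({"OH"}),
    "MET": frozenset({"SD"}),
}

#: Positively charged side-chain groups (His treated as charged, matching its
#: listing among the charged residues in composition statistics).
POSITIVE_GROUPS: dict[str, frozenset[str]] = {
    "ARG": frozenset({"NE", "NH1", "NH2"}),
    "LYS": frozenset({"NZ"}),
    "HIS": frozenset({"ND1", "NE2"}),
}

#: Negatively charged side-chain groups.
NEGATIVE_GROUPS: dict[str, frozenset[str]] = {
    "ASP": frozenset({"OD1", "OD2"}),
    "GLU": frozenset({"OE1", "OE2"}),
}

#: N-terminal amine / C-terminal carboxylate atoms, appended as charged
#: groups on terminal residues of each chain.
NTERM_POSITIVE_ATOMS: frozenset[str] = frozenset({"N"})
CTERM_NEGATIVE_ATOMS: frozenset[str] = frozenset({"O", "OXT"})

#: Aromatic ring atom sets for pi-pi stacking detection.
AROMATIC_RINGS: dict[str, tuple[frozenset[str], ...]] = {
    "PHE": (frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),),
    "TYR": (frozenset({"CG", "CD1", "CD2", "CE1", "CE2", "CZ"}),),
    "HIS": (frozenset({"CG", "ND1", "CD2", "CE1", "NE2"}),),
    "TRP": (
        frozenset({"CG", "CD1", "CD2", "NE1", "CE2"}),
        frozenset({"CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"}),
    ),
}
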