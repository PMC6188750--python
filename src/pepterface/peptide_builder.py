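"""Idealized peptide backbone construction from backbone dihedral angles.

Peptide query conformers for docking are built as idealized backbones in
three canonical conformations — alpha-helical (phi = -57, psi = -47),
extended (phi = -139, psi = -135) and polyproline (phi = -78, psi = 149) —
with trans peptide bonds (omega = 180) and ideal bond lengths and angles.
Atoms are placed by sequential internal-coordinate (NeRF) chain extension.
Side chains are represented by a single C-beta at ideal tetrahedral geometry
(L-configuration); docking engines rebuild full side chains themselves.

``measure_dihedrals`` validates any backbone via gemmi's dihedral primitive,
which keeps construction and measurement on independent code paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

from .chemistry import ONE_TO_THREE, STANDARD_AA
from .structure_model import AtomRecord, StructureModel

__all__ = ["ConformerSpec", "CONFORMERS", "build_peptide", "measure_dihedrals"]

# Ideal backbone geometry (Engh-Huber-style values), Angstrom / degrees.
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_N_CA_CB = 110.4


@dataclass(frozen=True)
class ConformerSpec:
    """Named backbone dihedral set in degrees (omega fixed trans)."""

    name: str
    phi: float
    psi: float
    omega: float = 180.0


CONFORMERS: dict[str, ConformerSpec] = {
    "alpha": ConformerSpec("alpha", phi=-57.0, psi=-47.0),
    "extended": ConformerSpec("extended", phi=-139.0, psi=-135.0),
    "polyproline": ConformerSpec("polyproline", phi=-78.0, psi=149.0),
}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom D from reference atoms A-B-C by internal coordinates.

    ``bond`` = |C-D|, ``angle_deg`` = angle B-C-D, ``torsion_deg`` = torsion
    A-B-C-D with the IUPAC sign convention.
    """
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # symmetric tetrahedral placement off the N-CA-C plane; the sign of the
    # out-of-plane component fixes the L-configuration
    u1 = (n - ca) / np.linalg.norm(n - ca)
    u2 = (c - ca) / np.linalg.norm(c - ca)
    bisector = u1 + u2
    bisector /= np.linalg.norm(bisector)
    normal = np.cross(u2, u1)
    normal /= np.linalg.norm(normal)
    alpha = math.cos(math.radians(ANGLE_N_CA_CB)) / float(bisector @ u1)
    alpha = max(-1.0, min(1.0, alpha))
    beta = math.sqrt(1.0 - alpha * alpha)
    direction = alpha * bisector + beta * normal
    return ca + BOND_CA_CB * direction / np.linalg.norm(direction)


def build_peptide(sequence: str, spec: ConformerSpec | str) -> StructureModel:
    """Build an idealized single-chain peptide backbone (N, CA, C, O, CB).

    Every internal residue receives exactly (spec.phi, spec.psi) and trans
    omega.  Chain id is "P" with a single placeholder receptor chain label
    never present in the atom list; residues are numbered from 1.
    """
    if isinstance(spec, str):
        spec = CONFORMERS[spec]
    sequence = sequence.upper()
    if len(sequence) < 2:
        raise ValueError("peptide must have at least 2 residues")
    if len(sequence) > 50:
        raise ValueError("peptide longer than 50 residues")
    bad = [a for a in sequence if a not in STANDARD_AA]
    if bad:
        raise ValueError(f"non-standard residue letter(s): {bad}")

    n_atoms: list[np.ndarray] = []
    ca_atoms: list[np.ndarray] = []
    c_atoms: list[np.ndarray] = []

    n0 = np.zeros(3)
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    c0 = _place(np.array([0.0, 1.0, 0.0]), n0, ca0, BOND_CA_C, ANGLE_N_CA_C, 0.0)
    n_atoms.append(n0)
    ca_atoms.append(ca0)
    c_atoms.append(c0)
    for _ in sequence[1:]:
        ni = _place(n_atoms[-1], ca_atoms[-1], c_atoms[-1],
                    BOND_C_N, ANGLE_CA_C_N, spec.psi)
        cai = _place(ca_atoms[-1], c_atoms[-1], ni,
                     BOND_N_CA, ANGLE_C_N_CA, spec.omega)
        ci = _place(c_atoms[-1], ni, cai, BOND_CA_C, ANGLE_N_CA_C, spec.phi)
        n_atoms.append(ni)
        ca_atoms.append(cai)
        c_atoms.append(ci)

    atoms: list[AtomRecord] = []
    serial = 0

    def add(name: str, element: str, pos: np.ndarray, residue: str, resnum: int) -> None:
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name=name, element=element, residue=residue,
            chain="P", resnum=resnum, icode="", coord=tuple(map(float, pos)),
        ))

    for i, letter in enumerate(sequence):
        res3 = ONE_TO_THREE[letter]
        resnum = i + 1
        add("N", "N", n_atoms[i], res3, resnum)
        add("CA", "C", ca_atoms[i], res3, resnum)
        add("C", "C", c_atoms[i], res3, resnum)
        # carbonyl O anti to the following amide N: torsion N-CA-C-O = psi+180
        o = _place(n_atoms[i], ca_atoms[i], c_atoms[i],
                   BOND_C_O, ANGLE_CA_C_O, spec.psi + 180.0)
        add("O", "O", o, res3, resnum)
        if letter != "G":
            add("CB", "C", _place_cb(n_atoms[i], ca_atoms[i], c_atoms[i]),
                res3, resnum)

    return StructureModel(
        atoms=atoms, peptide_chain="P", receptor_chains=frozenset({"_none_"})
    )


def helix_rise(model: StructureModel) -> float:
    """Mean axial rise per residue from C-alpha positions.

    The helix axis is estimated from the C-alpha second differences (radial
    vectors): cross products of successive second differences all point
    along the axis, which avoids the end-bias a principal-component fit
    shows on short helices.  Successive C-alpha positions are projected on
    that axis and the mean absolute step returned.
    """
    ca = np.array([a.coord for a in model.atoms if a.name == "CA"])
    if len(ca) < 5:
        raise ValueError("helix rise needs at least 5 C-alpha atoms")
    second = np.diff(np.diff(ca, axis=0), axis=0)
    crosses = np.cross(second[:-1], second[1:])
    norms = np.linalg.norm(crosses, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise ValueError("degenerate (collinear) C-alpha trace")
    axis = (crosses / norms).mean(axis=0)
    axis /= np.linalg.norm(axis)
    proj = ca @ axis
    return float(np.abs(np.diff(proj)).mean())


def _dihedral(p1, p2, p3, p4) -> float | None:
    """Torsion angle in degrees, or None for degenerate (collinear) input."""
    pts = [np.asarray(p, dtype=float) for p in (p1, p2, p3, p4)]
    b1, b2 = pts[1] - pts[0], pts[2] - pts[1]
    b3 = pts[3] - pts[2]
    if (np.linalg.norm(np.cross(b1, b2)) < 1e-9
            or np.linalg.norm(np.cross(b2, b3)) < 1e-9):
        return None
    rad = gemmi.calculate_dihedral(
        *(gemmi.Position(*p) for p in pts)
    )
    return math.degrees(rad)


def measure_dihedrals(model: StructureModel) -> list[dict[str, float | None]]:
    """Per-residue (phi, psi, omega) for the model's peptide chain.

    Terminal residues yield None for the dihedrals they lack (phi at the
    first residue, psi/omega at the last); a residue missing a backbone atom
    yields None for every dihedral that needs it.
    """
    chain = model.peptide_atoms or model.atoms
    by_res: dict[tuple, dict[str, tuple[float, float, float]]] = {}
    order: list[tuple] = []
    for a in chain:
        rid = a.residue_id
        if rid not in by_res:
            by_res[rid] = {}
            order.append(rid)
        if a.name in ("N", "CA", "C"):
            by_res[rid][a.name] = a.coord

    def get(i: int, name: str):
        if 0 <= i < len(order):
            return by_res[order[i]].get(name)
        return None

    out = []
    for i, rid in enumerate(order):
        entry: dict[str, float | None] = {"phi": None, "psi": None, "omega": None}
        quad = (get(i - 1, "C"), get(i, "N"), get(i, "CA"), get(i, "C"))
        if all(p is not None for p in quad):
            entry["phi"] = _dihedral(*quad)
        quad = (get(i, "N"), get(i, "CA"), get(i, "C"), get(i + 1, "N"))
        if all(p is not None for p in quad):
            entry["psi"] = _dihedral(*quad)
        quad = (get(i, "CA"), get(i, "C"), get(i + 1, "N"), get(i + 1, "CA"))
        if all(p is not None for p in quad):
            entry["omega"] = _dihedral(*quad)
        out.append(entry)
    return out
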