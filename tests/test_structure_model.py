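import math

import numpy as np
import pytest

from conftest import make_model, random_rotation
from pepterface.structure_model import (
    classify_atoms,
    euclid,
    read_pdb,
    write_pdb,
)

# minimal two-chain complex: Ala receptor residue (with an altLoc'd CB),
# Gly peptide residue, and a water that must be dropped
FIXTURE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB AALA A   1       2.000  -0.800   1.200  0.60  0.00           C
ATOM      6  CB BALA A   1       2.100  -0.900   1.300  0.40  0.00           C
TER
ATOM      7  N   GLY P   1       4.000   0.000   0.000  1.00  0.00           N
ATOM      8  CA  GLY P   1       5.458   0.000   0.000  1.00  0.00           C
ATOM      9  C   GLY P   1       6.009   1.420   0.000  1.00  0.00           C
ATOM     10  O   GLY P   1       5.251   2.390   0.000  1.00  0.00           O
TER
HETATM   11  O   HOH A 101      10.000  10.000  10.000  1.00  0.00           O
END
"""


@pytest.fixture
def fixture_path(tmp_path):
    path = tmp_path / "complex.pdb"
    path.write_text(FIXTURE_PDB)
    return path


class TestReadPdb:
    def test_roles_and_atom_count(self, fixture_path):
        model = read_pdb(fixture_path, peptide_chain="P")
        assert len(model.atoms) == 9  # water dropped, one altLoc kept
        assert model.peptide_chain == "P"
        assert model.receptor_chains == frozenset({"A"})
        assert len(model.peptide_atoms) == 4

    def test_highest_occupancy_altloc_kept(self, fixture_path):
        model = read_pdb(fixture_path, peptide_chain="P")
        cb = [a for a in model.atoms if a.name == "CB"]
        assert len(cb) == 1
        assert cb[0].occupancy == pytest.approx(0.60)
        assert cb[0].coord[0] == pytest.approx(2.000)

    def test_water_always_dropped(self, fixture_path):
        model = read_pdb(fixture_path, peptide_chain="P", keep_het=True)
        assert all(a.residue != "HOH" for a in model.atoms)

    def test_missing_peptide_chain_names_available_chains(self, fixture_path):
        with pytest.raises(ValueError, match="'A', 'P'"):
            read_pdb(fixture_path, peptide_chain="Z")


class TestEuclid:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0, 0, 0), (3, 4, 0), 5.0),
            ((1, 2, 3), (1, 2, 3), 0.0),
            ((1, 1, 1), (2, 2, 2), math.sqrt(3)),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert euclid(a, b) == pytest.approx(expected)

    def test_symmetric_and_triangle_inequality_on_random_triples(self, rng):
        pts = rng.normal(scale=10, size=(1000, 3, 3))
        for a, b, c in pts:
            assert euclid(a, b) == pytest.approx(euclid(b, a))
            assert euclid(a, c) <= euclid(a, b) + euclid(b, c) + 1e-9


ARG_FULL_H = (
    # backbone incl. amide H and HA
    [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("H", "H"), ("HA", "H")]
    # side chain: 7 heavy + 11 hydrogens of protonated arginine
    + [("CB", "C"), ("CG", "C"), ("CD", "C"), ("NE", "N"), ("CZ", "C"),
       ("NH1", "N"), ("NH2", "N")]
    + [(n, "H") for n in ("HB2", "HB3", "HG2", "HG3", "HD2", "HD3", "HE",
                          "HH11", "HH12", "HH21", "HH22")]
)


class TestClassifyAtoms:
    @staticmethod
    def single_residue_model(atom_spec, resname):
        rows = [(name, element, resname, "P", 1, (i * 2.0, 0, 0))
                for i, (name, element) in enumerate(atom_spec)]
        rows.append(("N", "N", "GLY", "A", 1, (500, 0, 0)))
        return make_model(rows)

    @pytest.mark.parametrize(
        "atoms, resname, side, backbone",
        [
            ([("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")], "GLY", 0, 4),
            ([("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O"), ("CB", "C")],
             "ALA", 1, 4),
        ],
    )
    def test_heavy_atom_residues(self, atoms, resname, side, backbone):
        model = self.single_residue_model(atoms, resname)
        counts = classify_atoms(model)["peptide"]
        assert counts["side_chain_heavy"] == side
        assert counts["backbone_heavy"] == backbone

    def test_protonated_arginine_hand_count(self):
        model = self.single_residue_model(ARG_FULL_H, "ARG")
        counts = classify_atoms(model)["peptide"]
        assert counts["side_chain_all"] == 18
        assert counts["backbone_all"] == 6
        assert counts["sc_bb_ratio_all"] == pytest.approx(3.0)

    def test_counts_invariant_under_rigid_body_motion(self, rng):
        model = self.single_residue_model(ARG_FULL_H, "ARG")
        moved = model.transformed(random_rotation(rng), rng.normal(size=3) * 20)
        assert classify_atoms(moved) == classify_atoms(model)


def test_write_read_round_trip_preserves_atoms_order_coords(tmp_path, fixture_path):
    model = read_pdb(fixture_path, peptide_chain="P")
    out = tmp_path / "roundtrip.pdb"
    write_pdb(model, out)
    back = read_pdb(out, peptide_chain="P")
    assert len(back.atoms) == len(model.atoms)
    for a, b in zip(model.atoms, back.atoms):
        assert (a.name, a.residue, a.chain, a.resnum) == (
            b.name, b.residue, b.chain, b.resnum,
        )
        assert a.coord == pytest.approx(b.coord, abs=1.5e-3)
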