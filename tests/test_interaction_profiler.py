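import numpy as np
import pytest

from conftest import make_model, random_rotation
from pepterface.interaction_profiler import (
    close_contacts,
    hydrogen_bonds,
    hydrophobic_contacts,
    pipi_stacks,
    profile,
    salt_bridges,
)
from pepterface.structure_model import euclid
from pepterface.synthetic_data import ComplexSpec, PlantedInteraction, make_complex


def pair_model(rec_atom, pep_atom, d, rec_res="PRO", pep_res="PRO"):
    """Two single-atom residues separated by d along x."""
    return make_model([
        (rec_atom[0], rec_atom[1], rec_res, "A", 1, (0, 0, 0)),
        (pep_atom[0], pep_atom[1], pep_res, "P", 1, (d, 0, 0)),
    ])


class TestCloseContacts:
    def test_single_planted_pair_detected(self):
        model = pair_model(("N", "N"), ("N", "N"), 3.9)
        assert len(close_contacts(model)) == 1

    def test_boundary_at_cutoff_is_inclusive(self):
        model = pair_model(("N", "N"), ("N", "N"), 4.0)
        contacts = close_contacts(model)
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(4.0)

    def test_separated_chains_make_no_contacts(self):
        model = pair_model(("N", "N"), ("N", "N"), 50.0)
        assert close_contacts(model) == []

    def test_tree_search_equals_all_pairs_oracle_on_random_fixtures(self, rng):
        for _ in range(30):
            n_r, n_p = rng.integers(5, 40, size=2)
            rows = [("N", "N", "PRO", "A", i + 1, xyz)
                    for i, xyz in enumerate(rng.uniform(0, 15, (n_r, 3)))]
            rows += [("N", "N", "PRO", "P", i + 1, xyz)
                     for i, xyz in enumerate(rng.uniform(0, 15, (n_p, 3)))]
            model = make_model(rows)
            got = {(c.receptor_atom.serial, c.peptide_atom.serial)
                   for c in close_contacts(model)}
            oracle = {
                (r.serial, p.serial)
                for r in model.receptor_atoms
                for p in model.peptide_atoms
                if euclid(r.coord, p.coord) <= 4.0
            }
            assert got == oracle


class TestHydrophobicContacts:
    def test_carbon_carbon_pair_detected(self):
        model = pair_model(("CB", "C"), ("CB", "C"), 3.8, "ALA", "ALA")
        assert len(hydrophobic_contacts(model)) == 1

    def test_nitrogen_oxygen_pair_excluded_but_still_close_contact(self):
        model = pair_model(("N", "N"), ("O", "O"), 3.0, "PRO", "GLY")
        assert hydrophobic_contacts(model) == []
        assert len(close_contacts(model)) == 1

    def test_distant_carbons_excluded(self):
        model = pair_model(("CB", "C"), ("CB", "C"), 4.5, "ALA", "ALA")
        assert hydrophobic_contacts(model) == []


def hbond_model(d, deviation, with_hydrogen=True):
    spec = ComplexSpec(planted=(
        PlantedInteraction("hbond", d, deviation=deviation),
    ))
    model, _ = make_complex(spec)
    if not with_hydrogen:
        model.atoms = [a for a in model.atoms if not a.is_hydrogen]
    return model


class TestHydrogenBonds:
    def test_planted_linear_bond_detected_with_donor_side(self):
        bonds = hydrogen_bonds(hbond_model(2.9, 5.0))
        assert len(bonds) == 1
        assert bonds[0].donor_side == "protein"
        assert bonds[0].deviation == pytest.approx(5.0, abs=1e-6)
        assert bonds[0].geometry_complete

    def test_angle_gate_rejects_bent_geometry(self):
        assert hydrogen_bonds(hbond_model(2.9, 45.0)) == []

    def test_distance_gate_rejects_long_pairs(self):
        assert hydrogen_bonds(hbond_model(4.2, 5.0)) == []

    def test_fallback_without_hydrogen_uses_stricter_distance(self):
        bonds = hydrogen_bonds(hbond_model(3.3, 5.0, with_hydrogen=False))
        assert len(bonds) == 1
        assert not bonds[0].geometry_complete
        assert bonds[0].deviation is None
        assert hydrogen_bonds(hbond_model(3.8, 5.0, with_hydrogen=False)) == []

    def test_every_bond_also_appears_in_close_contacts(self):
        model, _ = make_complex(ComplexSpec(planted=(
            PlantedInteraction("hbond", 2.9, deviation=5.0),
            PlantedInteraction("hbond", 3.9, deviation=30.0, donor_side="peptide"),
        )))
        contact_pairs = {
            frozenset((c.receptor_atom.serial, c.peptide_atom.serial))
            for c in close_contacts(model, cutoff=4.0)
        }
        for b in hydrogen_bonds(model):
            assert frozenset(
                (b.donor_atom.serial, b.acceptor_atom.serial)
            ) in contact_pairs


class TestSaltBridges:
    def test_lysine_glutamate_pair(self):
        model = pair_model(("NZ", "N"), ("OE1", "O"), 3.8, "LYS", "GLU")
        bridges = salt_bridges(model)
        assert len(bridges) == 1
        assert bridges[0].min_distance == pytest.approx(3.8)
        assert bridges[0].positive_side == "receptor"

    def test_like_charges_make_no_bridge(self):
        model = pair_model(("NH1", "N"), ("NZ", "N"), 3.5, "ARG", "LYS")
        assert salt_bridges(model) == []

    def test_peptide_cterminal_carboxylate_bridges_arginine(self):
        # Arg guanidinium against the peptide's C-terminal carboxylate O
        model = make_model([
            ("NH2", "N", "ARG", "A", 1, (0, 0, 0)),
            ("N", "N", "GLY", "P", 1, (3.4, 0, 9.0)),
            ("CA", "C", "GLY", "P", 1, (3.4, 0, 7.5)),
            ("C", "C", "GLY", "P", 1, (3.4, 0, 1.3)),
            ("O", "O", "GLY", "P", 1, (3.4, 0, 0.0)),
        ])
        bridges = salt_bridges(model)
        assert len(bridges) == 1
        assert bridges[0].negative_residue == ("P", 1, "")
        assert bridges[0].min_distance == pytest.approx(3.4)


class TestPiPiStacks:
    @staticmethod
    def ring_model(d, plane_angle):
        model, _ = make_complex(ComplexSpec(planted=(
            PlantedInteraction("pipi", d, plane_angle=plane_angle),
        )))
        return model

    def test_parallel_rings_stack(self):
        stacks = pipi_stacks(self.ring_model(4.0, 0.0))
        assert len(stacks) == 1
        assert stacks[0].centroid_distance == pytest.approx(4.0, abs=1e-9)
        assert stacks[0].plane_angle == pytest.approx(0.0, abs=1e-6)

    def test_tilted_rings_rejected_by_angle_gate(self):
        assert pipi_stacks(self.ring_model(4.0, 60.0)) == []

    def test_distant_centroids_rejected(self):
        assert pipi_stacks(self.ring_model(8.0, 0.0)) == []


FULL_SPEC = ComplexSpec(planted=(
    PlantedInteraction("close_contact", 3.9),
    PlantedInteraction("hydrophobic", 3.8),
    PlantedInteraction("hbond", 2.9, deviation=5.0),
    PlantedInteraction("salt_bridge", 3.8),
    PlantedInteraction("pipi", 4.2, plane_angle=10.0),
))


class TestInvariances:
    def test_detections_invariant_under_rigid_body_motion(self, rng):
        model, _ = make_complex(FULL_SPEC)
        moved = model.transformed(random_rotation(rng), rng.normal(size=3) * 30)
        for detector in (close_contacts, hydrophobic_contacts, salt_bridges,
                         pipi_stacks, hydrogen_bonds):
            before, after = detector(model), detector(moved)
            assert len(before) == len(after)
        d0 = [c.distance for c in close_contacts(model)]
        d1 = [c.distance for c in close_contacts(moved)]
        np.testing.assert_allclose(d0, d1, atol=1e-6)

    def test_role_swap_transposes_donor_tally_preserves_counts(self):
        model, _ = make_complex(ComplexSpec(planted=(
            PlantedInteraction("hbond", 2.9, deviation=5.0, donor_side="protein"),
            PlantedInteraction("hbond", 3.0, deviation=10.0, donor_side="peptide"),
            PlantedInteraction("salt_bridge", 3.8),
        )))
        swapped = model.swapped_roles()
        bonds, bonds_sw = hydrogen_bonds(model), hydrogen_bonds(swapped)
        assert len(bonds) == len(bonds_sw) == 2
        tally = sorted(b.donor_side for b in bonds)
        tally_sw = sorted(b.donor_side for b in bonds_sw)
        assert tally == tally_sw == ["peptide", "protein"]
        assert {b.donor_atom.chain for b in bonds} == {"A", "P"}
        assert len(salt_bridges(swapped)) == 1


class TestProfile:
    def test_participation_arithmetic_on_planted_truth(self):
        # peptide: 10 side-chain + 5 backbone atoms; 2 of each within 4 A
        rows = []
        sc_names = ["CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "CG1", "CG2", "CD"]
        for i, name in enumerate(sc_names):
            near = i < 2
            rows.append((name, "C", "LEU", "P", 1,
                         (3.5 if near else 50 + 5 * i, 3 * i, 0)))
        for i, name in enumerate(["N", "CA", "C", "O", "OXT"]):
            near = i < 2
            rows.append((name, name[0], "LEU", "P", 1,
                         (3.5 if near else 100 + 5 * i, 3 * i, 10)))
        rows.append(("N", "N", "PRO", "A", 1, (0, 0, 0)))
        rows.append(("N", "N", "PRO", "A", 2, (0, 3, 0)))
        rows.append(("N", "N", "PRO", "A", 3, (0, 0, 10)))
        rows.append(("N", "N", "PRO", "A", 4, (0, 3, 10)))
        result = profile(make_model(rows))
        assert result.participation_side_chain == pytest.approx(0.2)
        assert result.participation_backbone == pytest.approx(0.4)
        assert result.unique_sc_bb_ratio == pytest.approx(1.0)
        assert result.overall_sc_bb_ratio == pytest.approx(2.0)

    def test_bridge_and_stack_fixture_flags_both_category(self):
        model, _ = make_complex(ComplexSpec(planted=(
            PlantedInteraction("salt_bridge", 3.8),
            PlantedInteraction("pipi", 4.0),
        )))
        assert profile(model).interaction_category == "both"

    def test_contact_free_fixture_yields_zero_profile(self):
        model, _ = make_complex(ComplexSpec(planted=()))
        result = profile(model)
        assert result.n_close_contacts == 0
        assert result.n_hydrogen_bonds == 0
        assert result.interaction_category == "neither"
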