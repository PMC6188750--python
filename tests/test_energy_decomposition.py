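import numpy as np
import pandas as pd
import pytest

from pepterface.energy_decomposition import (
    ResidueContribution,
    SnapshotEnergies,
    contribution_summary,
    delta_g_bind,
    gibbs_sum,
    position_class,
    read_contributions_tsv,
    read_energies_tsv,
    select_prominent,
)
from pepterface.synthetic_data import make_decomposition


def snap(index, role, terms, ts=None):
    return SnapshotEnergies(index, role, *terms, ts=ts)


def triplet(index, dg):
    """complex/protein/peptide snapshots realizing per-snapshot dG."""
    return [
        snap(index, "protein", (0, 0, 0, 0, 0)),
        snap(index, "peptide", (0, 0, 0, 0, 0)),
        snap(index, "complex", (dg, 0, 0, 0, 0)),
    ]


class TestGibbsSum:
    def test_five_term_sum(self):
        assert gibbs_sum(snap(0, "complex", (1, 2, 3, 4, 5))) == 15

    def test_entropy_subtracted_when_present(self):
        assert gibbs_sum(snap(0, "complex", (1, 2, 3, 4, 5), ts=5)) == 10

    def test_zero_terms(self):
        assert gibbs_sum(snap(0, "complex", (0, 0, 0, 0, 0))) == 0

    def test_non_finite_term_rejected(self):
        with pytest.raises(ValueError):
            gibbs_sum(snap(0, "complex", (np.inf, 0, 0, 0, 0)))


class TestDeltaGBind:
    def test_mean_over_snapshots(self):
        snaps = triplet(0, -10) + triplet(1, -12) + triplet(2, -14)
        result = delta_g_bind(snaps)
        assert result.dg_bind == pytest.approx(-12)
        assert result.dg_sd == pytest.approx(2.0)
        assert result.n_snapshots == 3

    def test_single_snapshot_reports_zero_sd_with_warning(self):
        with pytest.warns(UserWarning):
            result = delta_g_bind(triplet(0, -5))
        assert result.dg_bind == -5 and result.dg_sd == 0.0

    def test_missing_role_names_offending_snapshot(self):
        snaps = triplet(0, -10) + triplet(1, -12)[:2]
        with pytest.raises(ValueError, match="snapshot 1"):
            delta_g_bind(snaps)

    def test_permutation_invariant_over_snapshot_order(self, rng):
        snaps = triplet(0, -10) + triplet(1, -12) + triplet(2, -14)
        shuffled = [snaps[i] for i in rng.permutation(len(snaps))]
        assert delta_g_bind(shuffled) == delta_g_bind(snaps)

    def test_zero_noise_recovers_planted_value_exactly(self):
        energies, _ = make_decomposition(
            -48.02, [("peptide", "LEU", 1, -48.02)], noise_sd=0.0, n_snapshots=10
        )
        assert delta_g_bind(energies).dg_bind == pytest.approx(-48.02, abs=1e-9)

    def test_noisy_recovery_within_sampling_error(self):
        recovered = []
        for rep in range(200):
            energies, _ = make_decomposition(
                -48.02, [("peptide", "LEU", 1, -48.02)],
                noise_sd=2.0, n_snapshots=100, seed=rep,
            )
            recovered.append(delta_g_bind(energies).dg_bind)
        se = 2.0 / np.sqrt(100 * 200)
        assert np.mean(recovered) == pytest.approx(-48.02, abs=3 * se)

    def test_subset_means_bracket_full_mean(self):
        snaps = sum((triplet(i, dg) for i, dg in
                     enumerate([-10, -11, -13, -18])), [])
        full = delta_g_bind(snaps).dg_bind
        lo = delta_g_bind(snaps[:6]).dg_bind
        hi = delta_g_bind(snaps[6:]).dg_bind
        assert min(lo, hi) <= full <= max(lo, hi)


def contribs(values, role="protein"):
    out = []
    for i, v in enumerate(values):
        pclass = position_class(i + 1, len(values)) if role == "peptide" else None
        out.append(ResidueContribution("S1", role, "ALA", i + 1, v, pclass))
    return out


class TestSelectProminent:
    def test_forty_percent_rule_on_hand_worked_example(self):
        selected = select_prominent(contribs([-10.0, -4.1, -3.9, 4.5]), 0.4)
        assert sorted(c.dg_contrib for c in selected) == [-10.0, -4.1, 4.5]

    def test_single_residue_always_selected(self):
        assert len(select_prominent(contribs([-2.0]), 0.4)) == 1

    def test_fraction_one_keeps_only_extremes(self):
        selected = select_prominent(contribs([-10.0, 10.0, -3.0]), 1.0)
        assert sorted(c.dg_contrib for c in selected) == [-10.0, 10.0]

    def test_all_zero_system_warns_and_selects_nothing(self):
        with pytest.warns(UserWarning):
            assert select_prominent(contribs([0.0, 0.0]), 0.4) == []

    def test_scale_invariance(self, rng):
        values = list(rng.normal(size=12))
        base = {c.res_index for c in select_prominent(contribs(values), 0.4)}
        scaled = {c.res_index
                  for c in select_prominent(contribs([7.3 * v for v in values]), 0.4)}
        assert base == scaled


class TestPositionClass:
    @pytest.mark.parametrize(
        "index, length, expected",
        [(1, 8, "N-terminal"), (8, 8, "C-terminal"), (4, 8, "internal")],
    )
    def test_classes(self, index, length, expected):
        assert position_class(index, length) == expected

    @pytest.mark.parametrize("index, length", [(0, 8), (9, 8)])
    def test_out_of_range_rejected(self, index, length):
        with pytest.raises(ValueError):
            position_class(index, length)


class TestContributionSummary:
    def test_per_type_count_and_mean(self):
        selected = [
            ResidueContribution("S1", "protein", "ARG", 10, -5.0),
            ResidueContribution("S2", "protein", "ARG", 22, -3.0),
        ]
        table = contribution_summary(selected)["by_type"]
        row = table[(table.chain_role == "protein") & (table.res_name == "ARG")]
        assert int(row["count"].iloc[0]) == 2
        assert row.mean_dg.iloc[0] == pytest.approx(-4.0)

    def test_positional_table_separates_termini(self):
        selected = [
            ResidueContribution("S1", "peptide", "ARG", 1, 2.0, "N-terminal"),
            ResidueContribution("S2", "peptide", "ARG", 4, -3.0, "internal"),
        ]
        table = contribution_summary(selected)["by_position"]
        assert set(table.position_class) == {"N-terminal", "internal"}
        internal = table[table.position_class == "internal"]
        assert internal.mean_dg.iloc[0] == pytest.approx(-3.0)


def test_residue_contributions_sum_to_system_dg():
    layout = [("protein", "ARG", 436, -20.0), ("protein", "ASP", 485, -10.0),
              ("peptide", "LEU", 1, 2.0), ("peptide", "PHE", 6, -20.02)]
    energies, contrib = make_decomposition(-48.02, layout, noise_sd=0.0,
                                           n_snapshots=5)
    total = sum(c.dg_contrib for c in contrib)
    assert abs(total - delta_g_bind(energies).dg_bind) < 1e-9


def test_tsv_readers_round_trip(tmp_path):
    layout = [("protein", "ARG", 436, -30.0), ("peptide", "LEU", 1, -18.02)]
    energies, contrib = make_decomposition(-48.02, layout, noise_sd=0.0,
                                           n_snapshots=3)
    epath = tmp_path / "e.tsv"
    pd.DataFrame([{
        "system_id": "SYN1", "snapshot": s.snapshot_index, "role": s.role,
        "e_bnd": s.e_bnd, "e_el": s.e_el, "e_vdw": s.e_vdw,
        "g_pol": s.g_pol, "g_np": s.g_np,
    } for s in energies]).to_csv(epath, sep="\t", index=False)
    rpath = tmp_path / "r.tsv"
    pd.DataFrame([{
        "system_id": c.system_id, "chain_role": c.chain_role,
        "res_name": c.res_name, "res_index": c.res_index,
        "dg_contrib": c.dg_contrib, "peptide_length": 1,
    } for c in contrib]).to_csv(rpath, sep="\t", index=False)

    systems = read_energies_tsv(epath)
    assert delta_g_bind(systems["SYN1"]).dg_bind == pytest.approx(-48.02)
    back = read_contributions_tsv(rpath)["SYN1"]
    assert back[1].position_class == "N-terminal"
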