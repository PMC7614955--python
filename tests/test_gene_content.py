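"""Presence/absence matrices, Dollo loss inference, topology ranking."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from nthiso.gene_content import (
    CHARACTERS,
    GeneRecord,
    PresenceAbsenceMatrix,
    brute_force_losses,
    build_matrix,
    compare_topologies,
    dollo_losses,
    root_paralog_count,
)
from nthiso.io import load_complements
from nthiso.synthetic import random_binary_tree


def _tree(newick: str) -> TreeNode:
    return TreeNode.read([newick])


def _matrix(present: dict[str, set[str]], lineages: list[str]) -> PresenceAbsenceMatrix:
    df = pd.DataFrame(
        {c: [l in present.get(c, set()) for l in lineages] for c in CHARACTERS},
        index=lineages,
    )
    return PresenceAbsenceMatrix(df)


class TestGeneRecord:
    def test_alpha_beta_cannot_carry_a_paralog_group(self):
        with pytest.raises(ValueError, match="paralogue group"):
            GeneRecord("L", "g", "ALPHA_BETA", "GROUP_I")

    def test_character_mapping(self):
        assert GeneRecord("L", "g", "ALPHA_BETA").character == "ALPHA_BETA"
        assert GeneRecord("L", "g", "BETA_ALPHA", "GROUP_II").character == "BETA_ALPHA_II"
        assert GeneRecord("L", "g", "BETA_ALPHA").character is None


class TestBuildMatrix:
    def test_packaged_complements_reproduce_the_survey_matrix(self, table2_matrix):
        built = build_matrix(load_complements(), table2_matrix.lineages)
        assert built == table2_matrix
        assert built.data.loc["Chromerida"].all()
        assert not built.data.loc["Piroplasmida"].any()

    def test_single_record_sets_single_cell(self):
        m = build_matrix([GeneRecord("L1", "g1", "ALPHA_BETA")], ["L1", "L2"])
        assert m.data.loc["L1", "ALPHA_BETA"]
        assert m.data.to_numpy().sum() == 1

    def test_duplicate_genes_are_idempotent(self):
        one = build_matrix([GeneRecord("L1", "g1", "ALPHA_BETA")], ["L1"])
        two = build_matrix(
            [GeneRecord("L1", "g1", "ALPHA_BETA"), GeneRecord("L1", "g2", "ALPHA_BETA")],
            ["L1"],
        )
        assert one == two

    def test_groupless_beta_alpha_record_warns_and_counts_nowhere(self):
        with pytest.warns(UserWarning, match="paralogue group"):
            m = build_matrix([GeneRecord("L1", "g1", "BETA_ALPHA")], ["L1"])
        assert not m.data.to_numpy().any()

    def test_record_outside_lineage_order_rejected(self):
        with pytest.raises(ValueError, match="L9"):
            build_matrix([GeneRecord("L9", "g1", "ALPHA_BETA")], ["L1"])


class TestDolloLosses:
    def test_character_present_everywhere_needs_no_loss(self):
        tree = _tree("((A,B),(C,D));")
        m = _matrix({"ALPHA_BETA": {"A", "B", "C", "D"}}, list("ABCD"))
        s = dollo_losses(tree, m, "ALPHA_BETA")
        assert (s.root_present, s.n_losses) == (True, 0)

    def test_absent_cherry_costs_one_loss_on_its_stem(self):
        tree = _tree("((A,B),(C,D));")
        m = _matrix({"ALPHA_BETA": {"A", "B"}}, list("ABCD"))
        s = dollo_losses(tree, m, "ALPHA_BETA")
        assert s.n_losses == 1
        assert s.loss_edges == frozenset([frozenset({"C", "D"})])

    def test_all_absent_defaults_to_never_observed(self):
        tree = _tree("((A,B),(C,D));")
        m = _matrix({}, list("ABCD"))
        s = dollo_losses(tree, m, "ALPHA_BETA")
        assert (s.root_present, s.n_losses) == (False, 0)
        assert "NEVER_OBSERVED" in s.flags

    def test_all_absent_with_asserted_ancestral_presence_is_one_root_loss(self):
        tree = _tree("((A,B),(C,D));")
        m = _matrix({}, list("ABCD"))
        s = dollo_losses(tree, m, "ALPHA_BETA", assert_ancestral_presence=True)
        assert s.n_losses == 1
        assert s.loss_edges == frozenset([frozenset("ABCD")])

    def test_polytomy_counts_each_absent_child_once(self):
        tree = _tree("(A,B,C,(D,E));")
        m = _matrix({"ALPHA_BETA": {"A"}}, list("ABCDE"))
        s = dollo_losses(tree, m, "ALPHA_BETA")
        assert s.n_losses == 3  # B, C and the (D,E) clade

    def test_leaf_mismatch_error_lists_the_difference(self):
        tree = _tree("((A,B),(C,E));")
        m = _matrix({}, list("ABCD"))
        with pytest.raises(ValueError, match="'D'"):
            dollo_losses(tree, m, "ALPHA_BETA")

    def test_table2_alpha_beta_is_single_loss_on_mathur(self, table2_matrix, topologies):
        s = dollo_losses(topologies["mathur"], table2_matrix, "ALPHA_BETA")
        assert s.n_losses == 1
        assert s.loss_edges == frozenset([
            frozenset({"Nephromycida", "Cryptosporidia", "Sarcocystidae",
                       "Eimeriidae", "Haemosporida", "Piroplasmida"})
        ])

    def test_alpha_beta_single_loss_invariant_to_nephromycida_placement(
        self, table2_matrix
    ):
        variants = [
            "(Chromerida,((Gregarinia,Marosporida),((Nephromycida,Cryptosporidia),"
            "((Sarcocystidae,Eimeriidae),(Haemosporida,Piroplasmida)))));",
            "(Chromerida,((Gregarinia,Marosporida),(Cryptosporidia,((Sarcocystidae,"
            "(Nephromycida,Eimeriidae)),(Haemosporida,Piroplasmida)))));",
            "(Chromerida,((Gregarinia,Marosporida),(Cryptosporidia,((Sarcocystidae,"
            "Eimeriidae),(Nephromycida,(Haemosporida,Piroplasmida))))));",
        ]
        for nwk in variants:
            s = dollo_losses(_tree(nwk), table2_matrix, "ALPHA_BETA")
            assert s.n_losses == 1

    def test_agrees_with_brute_force_on_random_cases(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(2, 8))
            leaves = [f"T{k}" for k in range(n)]
            tree = random_binary_tree(leaves, rng)
            present = {l for l in leaves if rng.random() < 0.5}
            m = _matrix({"ALPHA_BETA": present}, leaves)
            s = dollo_losses(tree, m, "ALPHA_BETA", assert_ancestral_presence=True)
            assert s.n_losses == brute_force_losses(tree, present)

    def test_gaining_a_present_tip_inside_an_absent_clade_never_reduces_losses(self):
        rng = np.random.default_rng(29)
        for _ in range(50):
            n = int(rng.integers(3, 8))
            leaves = [f"T{k}" for k in range(n)]
            tree = random_binary_tree(leaves, rng)
            present = {l for l in leaves if rng.random() < 0.4}
            absent = [l for l in leaves if l not in present]
            if not absent or not present:
                continue
            m = _matrix({"ALPHA_BETA": present}, leaves)
            scenario = dollo_losses(tree, m, "ALPHA_BETA")
            # flip a tip inside a lost clade of >= 2 tips (a lone-tip loss
            # would simply vanish)
            clades = [e for e in scenario.loss_edges if len(e) >= 2]
            if not clades:
                continue
            tip = sorted(clades[0])[0]
            m2 = _matrix({"ALPHA_BETA": present | {tip}}, leaves)
            after = dollo_losses(tree, m2, "ALPHA_BETA").n_losses
            assert after >= scenario.n_losses


class TestRootParalogCount:
    def test_apicomplexan_chromerid_root_keeps_two_paralogues(
        self, table2_matrix, topologies
    ):
        for tree in topologies.values():
            assert root_paralog_count(
                tree, table2_matrix, ["BETA_ALPHA_I", "BETA_ALPHA_II"]
            ) == 2

    def test_all_false_matrix_counts_zero(self):
        tree = _tree("((A,B),(C,D));")
        m = _matrix({}, list("ABCD"))
        assert root_paralog_count(tree, m, list(CHARACTERS)) == 0

    def test_single_present_tip_counts_one(self):
        tree = _tree("((A,B),(C,D));")
        m = _matrix({"BETA_ALPHA_I": {"C"}}, list("ABCD"))
        assert root_paralog_count(tree, m, list(CHARACTERS)) == 1


class TestCompareTopologies:
    def test_ranking_sorted_ascending_with_per_character_columns(
        self, table2_matrix, topologies
    ):
        ranking = compare_topologies(table2_matrix, topologies)
        assert list(ranking.columns) == [
            "topology", *table2_matrix.characters, "total_losses"
        ]
        totals = list(ranking["total_losses"])
        assert totals == sorted(totals)

    def test_identical_topologies_get_identical_rows(self, table2_matrix, topologies):
        twins = {"x_copy": topologies["mathur"], "a_copy": topologies["mathur"]}
        ranking = compare_topologies(table2_matrix, twins)
        a, x = ranking.drop(columns="topology").to_numpy()
        assert (a == x).all()
        # ties broken by name
        assert list(ranking["topology"]) == ["a_copy", "x_copy"]

    def test_single_topology_gives_single_row(self, table2_matrix, topologies):
        ranking = compare_topologies(table2_matrix, {"only": topologies["mathur"]})
        assert len(ranking) == 1


class TestBruteForce:
    def test_all_present_costs_nothing(self):
        tree = _tree("((A,B),(C,D));")
        assert brute_force_losses(tree, set("ABCD")) == 0

    def test_all_absent_is_one_root_edge_loss(self):
        tree = _tree("((A,B),(C,D));")
        assert brute_force_losses(tree, set()) == 1

    def test_large_tree_rejected(self):
        tree = _tree("((((A,B),(C,D)),(E,F)),(G,H));")
        with pytest.raises(ValueError, match="12"):
            brute_force_losses(tree, {"A"})
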