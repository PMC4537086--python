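"""Tree analytics: TMRCA, root height, basal-node age, monophyly, Newick I/O."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coaldate import (
    CladeQuery,
    SimulationConfig,
    Sorting,
    basal_node_age,
    classify_sorting,
    parse_newick,
    root_height,
    simulate_genealogy,
    tmrca,
    write_newick,
)
from coaldate.coalescent_core import Genealogy, GenealogyNode
from coaldate.errors import (
    InvalidQueryError,
    MissingTaxonError,
    NewickParseError,
    UndefinedQuantityError,
)
from coaldate.tree_metrics import metrics_dataframe


class TestTmrca:
    def test_worked_tree_values(self, trees):
        cherry = trees["cherry3"]
        assert tmrca(cherry, {"A", "B"}) == pytest.approx(1.0)
        assert tmrca(cherry, {"A", "C"}) == pytest.approx(2.0)
        assert tmrca(cherry, {"A", "B", "C"}) == root_height(cherry)

    def test_singleton_query_is_zero(self, trees):
        assert tmrca(trees["cherry3"], {"A"}) == 0.0

    def test_unknown_label_raises_naming_it(self, trees):
        with pytest.raises(MissingTaxonError, match="Zed"):
            tmrca(trees["cherry3"], {"A", "Zed"})

    def test_monotone_under_query_inclusion(self, deep_trees_small):
        for tree in deep_trees_small[:20]:
            labels = sorted(tree.leaf_labels)
            for k in range(1, len(labels)):
                assert tmrca(tree, labels[:k]) <= tmrca(tree, labels[: k + 1])
            assert tmrca(tree, labels) == root_height(tree)


class TestBasalNodeAge:
    def test_worked_trees(self, trees):
        assert basal_node_age(trees["cherry3"]) == pytest.approx(1.0)
        assert basal_node_age(trees["ladder4"]) == pytest.approx(2.0)

    def test_undefined_for_two_leaf_tree(self):
        two = Genealogy(
            root=GenealogyNode(
                age=1.0, children=(GenealogyNode(label="a"), GenealogyNode(label="b"))
            )
        )
        with pytest.raises(UndefinedQuantityError):
            basal_node_age(two)

    def test_always_strictly_below_root_height(self, deep_trees_small, recent_trees_small):
        for tree in deep_trees_small + recent_trees_small:
            assert basal_node_age(tree) < root_height(tree)


class TestClassifySorting:
    def test_monophyletic_example(self, trees):
        status = classify_sorting(trees["mono3"], {"X1", "X2"})
        assert status.status is Sorting.MONOPHYLETIC
        assert status.n_intruders == 0

    def test_paraphyletic_example(self, trees):
        status = classify_sorting(trees["para3"], {"X1", "X2"})
        assert status.status is Sorting.NON_MONOPHYLETIC
        assert status.n_intruders == 1

    def test_singleton_is_vacuously_monophyletic(self, trees):
        assert classify_sorting(trees["cherry3"], {"A"}).is_monophyletic

    def test_full_leaf_set_rejected(self, trees):
        with pytest.raises(InvalidQueryError):
            classify_sorting(trees["cherry3"], {"A", "B", "C"})

    def test_agrees_with_brute_force_on_four_leaf_trees(self):
        """Brute force: monophyly iff the MRCA's descendant set equals the query."""
        for seed in range(60):
            cfg = SimulationConfig(pop_sizes=(2, 2), t_join=0.2, seed=seed)
            tree = simulate_genealogy(cfg, 0)
            ingroup = {"X1", "X2"}
            # independent check: smallest clade containing the ingroup
            best = None
            for node in tree.root.postorder():
                below = {leaf.label for leaf in node.leaves()}
                if ingroup <= below and (best is None or len(below) < len(best)):
                    best = below
            expected = best == ingroup
            assert classify_sorting(tree, ingroup).is_monophyletic is expected

    def test_deep_divergence_is_essentially_always_monophyletic(self):
        cfg = SimulationConfig(pop_sizes=(1, 10), t_join=10.0, n_reps=2000, seed=17)
        hits = sum(
            classify_sorting(simulate_genealogy(cfg, i), cfg.ingroup_labels).is_monophyletic
            for i in range(cfg.n_reps)
        )
        assert hits / cfg.n_reps >= 0.999


class TestNewick:
    def test_parse_worked_string(self):
        tree = parse_newick("((A:1,B:1):1,C:2);")
        assert root_height(tree) == pytest.approx(2.0)
        assert tmrca(tree, {"A", "B"}) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_round_trip_preserves_metrics(self, seed):
        cfg = SimulationConfig(pop_sizes=(1, 5), t_join=0.3, seed=seed)
        tree = simulate_genealogy(cfg, 0)
        again = parse_newick(write_newick(tree))
        assert set(again.leaf_labels) == set(tree.leaf_labels)
        assert root_height(again) == pytest.approx(root_height(tree), abs=1e-5)
        assert basal_node_age(again) == pytest.approx(basal_node_age(tree), abs=1e-5)
        assert (
            classify_sorting(again, cfg.ingroup_labels).is_monophyletic
            == classify_sorting(tree, cfg.ingroup_labels).is_monophyletic
        )

    def test_malformed_input_raises_parse_error(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A:1,B:1:1,C:2);")

    def test_non_ultrametric_input_flagged(self):
        with pytest.raises(NewickParseError, match="ultrametric"):
            parse_newick("((A:1,B:2):1,C:2);")

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(NewickParseError):
            parse_newick("((A,B),C);")


def test_metrics_dataframe_columns(deep_trees_small):
    frame = metrics_dataframe(deep_trees_small[:10], CladeQuery([f"X{i}" for i in range(1, 11)]))
    assert len(frame) == 10
    assert set(frame.columns) >= {
        "tmrca_ingroup_4N0",
        "root_height_4N0",
        "basal_node_age_4N0",
        "sorting_status",
    }
    assert (frame["tmrca_ingroup_4N0"] <= frame["root_height_4N0"]).all()
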