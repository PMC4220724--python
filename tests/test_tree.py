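import numpy as np
import pytest

import phylocomm as pc
from phylocomm.tree import TreeError

from conftest import random_tree_newick


class TestReadWrite:
    def test_basic_parse_counts(self, balanced_tree):
        assert sorted(pc.tip_labels(balanced_tree)) == ["A", "B", "C", "D"]
        assert pc.total_tree_length(balanced_tree) == 6.0

    def test_polytomy_preserved(self):
        t = pc.read_newick("((A:1,B:2,C:3):1,D:4);")
        degrees = sorted(len(n.child_nodes()) for n in t.preorder_internal_node_iter())
        assert degrees == [2, 3]

    def test_unifurcation_suppressed_with_warning(self):
        with pytest.warns(UserWarning, match="unifurcation"):
            t = pc.read_newick("((A:1):2,B:1);")
        dm = pc.patristic_distances(t)
        assert dm.distance("A", "B") == 4.0

    def test_malformed_input_raises(self):
        with pytest.raises(pc.NewickParseError, match="column"):
            pc.read_newick("((A:1,B:1;")

    def test_duplicate_labels_named(self):
        with pytest.raises((TreeError, pc.NewickParseError), match="A"):
            pc.read_newick("((A:1,A:2):1,B:1);")

    def test_missing_length_flag(self):
        with pytest.raises(TreeError, match="missing"):
            pc.read_newick("((A,B),C);")
        t = pc.read_newick("((A,B),C);", missing_length="zero")
        assert pc.total_tree_length(t) == 0.0

    def test_quoted_label_roundtrip(self):
        t = pc.read_newick("('sp. nov':1,B:1);")
        out = pc.write_newick(t)
        t2 = pc.read_newick(out)
        assert sorted(pc.tip_labels(t2)) == ["B", "sp. nov"]

    def test_precision_formatting(self):
        t = pc.read_newick(f"(A:{1 / 3},B:1);")
        assert "0.333" in pc.write_newick(t, precision=3)

    @pytest.mark.parametrize("seed", range(20))
    def test_roundtrip_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        t = pc.read_newick(random_tree_newick(rng, int(rng.integers(3, 20))))
        t2 = pc.read_newick(pc.write_newick(t, precision=10))
        d1 = pc.patristic_distances(t)
        d2 = pc.patristic_distances(t2)
        assert d1.labels == d2.labels
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-9)


class TestPatristicDistances:
    def test_hand_values(self, balanced_tree):
        dm = pc.patristic_distances(balanced_tree)
        assert dm.distance("A", "B") == 2.0
        assert dm.distance("A", "C") == 4.0
        assert dm.distance("C", "D") == 2.0
        assert np.all(np.diag(dm.values) == 0)

    def test_star_tree(self):
        dm = pc.patristic_distances(pc.read_newick("(A:1,B:1,C:1);"))
        off = dm.values[~np.eye(3, dtype=bool)]
        assert np.all(off == 2.0)

    def test_subset_and_unknown_tip(self, balanced_tree):
        dm = pc.patristic_distances(balanced_tree, tips=["A", "C"])
        assert dm.labels == ["A", "C"]
        assert dm.values[0, 1] == 4.0
        with pytest.raises(TreeError, match="nope"):
            pc.patristic_distances(balanced_tree, tips=["A", "nope"])

    def test_symmetry_and_triangle(self, rng):
        t = pc.read_newick(random_tree_newick(rng, 12))
        dm = pc.patristic_distances(t)
        np.testing.assert_array_equal(dm.values, dm.values.T)
        d = dm.values
        n = d.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestPrune:
    def test_hand_case_through_root(self, balanced_tree):
        p = pc.prune_to_tips(balanced_tree, {"A", "C"})
        assert pc.tip_labels(p) == ["A", "C"]
        assert pc.total_tree_length(p) == 4.0
        assert pc.patristic_distances(p).distance("A", "C") == 4.0

    def test_full_set_identity(self, balanced_tree):
        p = pc.prune_to_tips(balanced_tree, {"A", "B", "C", "D"})
        np.testing.assert_array_equal(
            pc.patristic_distances(p).values,
            pc.patristic_distances(balanced_tree).values,
        )
        assert pc.total_tree_length(p) == 6.0

    def test_root_stub_dropped_by_default(self):
        t = pc.read_newick("((A:1,B:1):1,C:2);")
        p = pc.prune_to_tips(t, {"A", "B"})
        assert pc.total_tree_length(p) == 2.0  # Steiner length, stub dropped
        stub = pc.prune_to_tips(t, {"A", "B"}, keep_root_stub=True)
        assert stub.seed_node.edge.length == 1.0

    def test_errors(self, balanced_tree):
        with pytest.raises(TreeError):
            pc.prune_to_tips(balanced_tree, {"A"})
        with pytest.raises(TreeError, match="Z"):
            pc.prune_to_tips(balanced_tree, {"A", "Z"})

    @pytest.mark.parametrize("seed", range(25))
    def test_distances_preserved_random(self, seed):
        rng = np.random.default_rng(1000 + seed)
        n = int(rng.integers(5, 25))
        t = pc.read_newick(random_tree_newick(rng, n))
        labels = pc.tip_labels(t)
        k = int(rng.integers(2, n))
        subset = sorted(rng.choice(labels, size=k, replace=False))
        before = pc.patristic_distances(t, tips=subset)
        after = pc.patristic_distances(pc.prune_to_tips(t, subset))
        assert before.labels == after.labels
        np.testing.assert_allclose(before.values, after.values, rtol=1e-12, atol=1e-12)


class TestCollapse:
    def test_zero_edge_becomes_polytomy(self):
        t = pc.read_newick("((A:1,B:1):0,(C:1,D:1):1);")
        c = pc.collapse_short_edges(t, 0)
        assert len(c.seed_node.child_nodes()) == 3
        assert pc.resolution_fraction(c) == pc.resolution_fraction(t)

    def test_positive_tree_unchanged(self, balanced_tree):
        c = pc.collapse_short_edges(balanced_tree, 0)
        np.testing.assert_array_equal(
            pc.patristic_distances(c).values,
            pc.patristic_distances(balanced_tree).values,
        )

    def test_all_zero_internal_gives_star(self):
        t = pc.read_newick("(((A:1,B:1):0,C:1):0,D:1);")
        c = pc.collapse_short_edges(t, 0)
        assert len(c.seed_node.child_nodes()) == 4

    def test_group_collapse_preserves_depths(self):
        t = pc.read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        g = pc.collapse_group_to_polytomy(t, {"A", "B", "C"})
        assert pc.write_newick(g, 0).startswith("((A:2,B:2,C:2):1,D:3)")
        for tree in (t, g):
            dm = pc.patristic_distances(tree)
            assert dm.distance("A", "D") == 6.0

    def test_group_collapse_cherry_noop(self, balanced_tree):
        g = pc.collapse_group_to_polytomy(balanced_tree, {"C", "D"})
        np.testing.assert_array_equal(
            pc.patristic_distances(g).values,
            pc.patristic_distances(balanced_tree).values,
        )

    def test_group_collapse_non_monophyletic(self):
        t = pc.read_newick("(((A:1,B:1):1,C:2):1,D:3);")
        with pytest.raises(TreeError, match="monophyletic"):
            pc.collapse_group_to_polytomy(t, {"A", "D"})

    @pytest.mark.parametrize("seed", range(10))
    def test_group_collapse_root_to_tip_invariant(self, seed):
        rng = np.random.default_rng(2000 + seed)
        t = pc.read_newick(random_tree_newick(rng, 12))
        # pick a random internal clade
        internals = [
            n
            for n in t.preorder_internal_node_iter()
            if n is not t.seed_node
        ]
        clade = internals[int(rng.integers(len(internals)))]
        tips = [l.taxon.label for l in clade.leaf_iter()]
        g = pc.collapse_group_to_polytomy(t, tips)
        ref = pc.patristic_distances(t)
        got = pc.patristic_distances(g)
        # distances to tips outside the group are preserved (root-to-tip
        # paths unchanged); within-group structure is flattened
        outside = sorted(set(ref.labels) - set(tips))
        for a in tips:
            for b in outside:
                assert got.distance(a, b) == pytest.approx(ref.distance(a, b), abs=1e-12)


class TestResolutionMonophyly:
    def test_resolution_hand_cases(self, balanced_tree):
        half = pc.read_newick("((A:1,B:1):0,(C:1,D:1):1);")
        assert pc.resolution_fraction(half) == 0.5
        assert pc.resolution_fraction(balanced_tree) == 1.0
        assert pc.resolution_fraction(pc.read_newick("(A:1,B:1,C:1);")) == 0.0
        with pytest.raises(TreeError):
            pc.resolution_fraction(pc.read_newick("(A:1,B:1);"))

    def test_resolution_capped_for_polytomy_with_positive_edges(self):
        # 4 tips, one positive internal edge out of n-2=2 possible
        t = pc.read_newick("((A:1,B:1,C:1):1,D:1);")
        assert pc.resolution_fraction(t) == 0.5

    def test_monophyly_hand_cases(self, balanced_tree):
        tax_good = {s: (g, "f", "o") for s, g in zip("ABCD", "1122")}
        tax_bad = {s: (g, "f", "o") for s, g in zip("ABCD", "1212")}
        assert pc.monophyly_rate(balanced_tree, tax_good, "genus") == 1.0
        assert pc.monophyly_rate(balanced_tree, tax_bad, "genus") == 0.0
        whole = {s: ("g", "f", "o") for s in "ABCD"}
        assert pc.monophyly_rate(balanced_tree, whole, "family") == 1.0

    def test_monophyly_scale_invariant(self, rng):
        t = pc.read_newick(random_tree_newick(rng, 10))
        labels = pc.tip_labels(t)
        tax = {l: (f"g{i % 3}", "f", "o") for i, l in enumerate(labels)}
        before = pc.monophyly_rate(t, tax, "genus")
        for n in t.preorder_node_iter():
            if n.edge.length is not None:
                n.edge.length *= 7.5
        assert pc.monophyly_rate(t, tax, "genus") == before

    def test_monophyly_missing_tip_named(self, balanced_tree):
        with pytest.raises(TreeError, match="D"):
            pc.monophyly_rate(balanced_tree, {s: ("g", "f", "o") for s in "ABC"}, "genus")


def test_read_taxonomy_roundtrip():
    text = "species,genus,family,order\nA,g1,f1,o1\nB,g1,f1,o1\n"
    tax = pc.read_taxonomy(text)
    assert tax == {"A": ("g1", "f1", "o1"), "B": ("g1", "f1", "o1")}
    with pytest.raises(ValueError, match="duplicate"):
        pc.read_taxonomy("species,genus,family,order\nA,g,f,o\nA,g,f,o\n")
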