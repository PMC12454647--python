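import itertools

import numpy as np
import pytest

import convfuse as cf
from convfuse.phylo import _leaf_sets, sister_clade


def read(data):
    return cf.read_newick(None, data=data)


def brute_force_monophyly(tree, tip_set):
    """Oracle: enumerate every node's descendant set."""
    return frozenset(tip_set) in set(_leaf_sets(tree).values())


class TestRooting:
    def test_quartet_outgroup(self):
        tree = read("((a:1,b:1):1,(o:1,c:1):1);")
        rooted = cf.root_at_outgroup(tree, ["o"])
        kids = rooted.seed_node.child_nodes()
        sides = sorted(
            tuple(sorted(l.taxon.label for l in k.leaf_iter())) for k in kids
        )
        assert sides == [("a", "b", "c"), ("o",)]

    def test_outgroup_cannot_be_everything(self):
        tree = read("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="full tip set"):
            cf.root_at_outgroup(tree, ["a", "b", "c"])

    def test_non_separable_outgroup_rejected(self):
        tree = read("((a:1,o1:1):1,(o2:1,c:1):1);")
        with pytest.raises(ValueError, match="separable"):
            cf.root_at_outgroup(tree, ["o1", "o2"])

    def test_supports_map_to_same_bipartitions(self):
        # DERIVED oracle: compare support-by-bipartition sets before/after
        tree = read("(((a:1,b:1)90:1,(c:1,d:1)85:1)70:1,(o:1,e:1)60:1);")
        all_tips = frozenset("abcdeo")

        def split_supports(t):
            out = {}
            sets = _leaf_sets(t)
            for node in t.preorder_node_iter():
                sup = cf.edge_support(node)
                if sup is None:
                    continue
                side = sets[id(node)]
                key = min(side, all_tips - side, key=sorted)
                if 1 < len(key) < len(all_tips) - 1:
                    out[key] = sup
            return out

        before = split_supports(tree)
        rooted = cf.root_at_outgroup(tree, ["o"])
        after = split_supports(rooted)
        assert before == after


class TestMonophyly:
    def test_singleton_is_monophyletic(self):
        tree = read("((a:1,b:1)90:1,c:1);")
        assert cf.is_monophyletic(tree, ["a"]).monophyletic

    def test_full_tip_set_is_monophyletic(self):
        tree = read("((a:1,b:1)90:1,c:1);")
        assert cf.is_monophyletic(tree, ["a", "b", "c"]).monophyletic

    def test_defining_edge_support_reported(self):
        tree = read("((a:1,b:1)90:1,c:1);")
        res = cf.is_monophyletic(tree, ["a", "b"])
        assert res.monophyletic and res.defining_edge_support == 90

    def test_unknown_tip_rejected(self):
        tree = read("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="unknown"):
            cf.is_monophyletic(tree, ["a", "z"])

    def test_matches_descendant_set_oracle_on_random_trees(self):
        for seed in range(25):
            tree = cf.simulate_species_tree(8, seed=seed)
            tips = cf.tip_labels(tree)
            for r in (2, 3, 7):
                for sub in itertools.combinations(tips, r):
                    assert (
                        cf.is_monophyletic(tree, list(sub)).monophyletic
                        == brute_force_monophyly(tree, sub)
                    )

    def test_complement_equivalence_on_unrooted_reading(self):
        # for a bifurcating ROOT, a root child's clade and its complement are
        # the same unrooted split, so both read as monophyletic
        tree = read("((a:1,b:1):1,(c:1,d:1):1);")
        assert cf.is_monophyletic(tree, ["a", "b"]).monophyletic
        assert cf.is_monophyletic(tree, ["c", "d"]).monophyletic


class TestSisterClade:
    def test_cherry_sisters_with_support(self):
        tree = read("((A1:1,A2:1)100:1,(B1:1,B2:1)100:1);")
        res = sister_clade(tree, ["A1", "A2"], threshold=95)
        assert res.sister_labels == {"B1": 1, "B2": 1}
        assert res.sister_support == 100 and not res.unresolved

    def test_labeling_aggregates_families(self):
        tree = read("((A1:1,A2:1)100:1,(B1:1,B2:1)100:1);")
        res = sister_clade(tree, ["A1", "A2"], labeling={"B1": "fam", "B2": "fam"})
        assert res.sister_labels == {"fam": 2}

    def test_low_support_flags_unresolved(self):
        tree = read("(((A1:1,A2:1)100:1,(B1:1,B2:1)100:1)80:1,o:1);")
        res = sister_clade(tree, ["A1", "A2"], threshold=95)
        assert res.unresolved  # parent edge support 80 < 95

    def test_polytomy_pools_all_siblings(self):
        tree = read("((A1:1,A2:1)100:1,b:1,c:1);")
        res = sister_clade(tree, ["A1", "A2"])
        assert res.polytomy and res.sister_labels == {"b": 1, "c": 1}

    def test_full_set_has_no_sister(self):
        tree = read("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError, match="sister"):
            sister_clade(tree, ["a", "b", "c"])


def two_clade_forest(sup_inner="100", sup_outer="100"):
    """((A,W1),(B,W2)) domain-tree shape with configurable supports."""
    return read(
        f"(((A1:1,A2:1){sup_inner}:1,(W1:1,W2:1){sup_inner}:1){sup_outer}:1,"
        f"((B1:1,B2:1){sup_inner}:1,(W3:1,W4:1){sup_inner}:1){sup_outer}:1);"
    )


LABELS = {"A1": "famA", "A2": "famA", "B1": "famB", "B2": "famB",
          "W1": "w", "W2": "w", "W3": "w", "W4": "w"}


class TestVerdict:
    def test_independent_origin_on_separated_clades(self):
        t = two_clade_forest()
        assert cf.convergence_verdict(t, t, LABELS, LABELS, "famA", "famB") == "independent_origin"

    def test_low_support_separation_is_unresolved(self):
        t = two_clade_forest(sup_inner="50", sup_outer="50")
        assert cf.convergence_verdict(t, t, LABELS, LABELS, "famA", "famB") == "unresolved"

    def test_shared_origin_when_union_monophyletic(self):
        t = read("(((A1:1,A2:1)100:1,(B1:1,B2:1)100:1)100:1,(W1:1,W2:1)100:1);")
        labels = {k: v for k, v in LABELS.items() if k in "A1 A2 B1 B2 W1 W2".split()}
        assert cf.convergence_verdict(t, t, labels, labels, "famA", "famB") == "shared_origin"

    def test_disagreement_between_trees_is_unresolved(self):
        t_good = two_clade_forest()
        # families interleaved with outsiders: nothing is monophyletic
        t_mixed = read(
            "(((A1:1,B1:1)100:1,(W1:1,W2:1)100:1)100:1,"
            "((A2:1,B2:1)100:1,(W3:1,W4:1)100:1)100:1);"
        )
        assert (
            cf.convergence_verdict(t_good, t_mixed, LABELS, LABELS, "famA", "famB")
            == "unresolved"
        )

    def test_missing_family_rejected(self):
        t = two_clade_forest()
        labels = {k: ("famA" if v == "famA" else "w") for k, v in LABELS.items()}
        with pytest.raises(ValueError, match="famB"):
            cf.convergence_verdict(t, t, labels, labels, "famA", "famB")

    def test_invariant_under_child_order_permutation(self):
        t1 = two_clade_forest()
        t2 = read(
            "(((W4:1,W3:1)100:1,(B2:1,B1:1)100:1)100:1,"
            "((W2:1,W1:1)100:1,(A2:1,A1:1)100:1)100:1);"
        )
        assert (
            cf.convergence_verdict(t1, t1, LABELS, LABELS, "famA", "famB")
            == cf.convergence_verdict(t2, t2, LABELS, LABELS, "famA", "famB")
        )

    def test_min_separating_edges_configurable(self):
        t = two_clade_forest(sup_inner="50", sup_outer="100")
        assert cf.convergence_verdict(
            t, t, LABELS, LABELS, "famA", "famB", min_separating_edges=2
        ) == "independent_origin"
        assert cf.convergence_verdict(
            t, t, LABELS, LABELS, "famA", "famB", min_separating_edges=3
        ) == "unresolved"
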