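import itertools

import dendropy
import numpy as np
import pytest
from scipy.linalg import expm

import convfuse as cf
from convfuse.coevolution import (
    STATES,
    TreeIndex,
    _transition_matrices,
    build_rate_matrix,
    stationary_distribution,
)
from convfuse.coevolution import test_interaction as interaction_test


def brute_force_loglik(tree, tip_states, Q, prior):
    """Oracle: sum the joint probability over every assignment of internal
    node states (no pruning)."""
    nodes = list(tree.postorder_node_iter())
    internals = [n for n in nodes if not n.is_leaf()]
    tips = [n for n in nodes if n.is_leaf()]
    P = {id(n): expm(Q * (n.edge.length or 0.0)) for n in nodes}
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internals)):
        state = {id(n): s for n, s in zip(internals, assign)}
        for n in tips:
            state[id(n)] = tip_states[n.taxon.label]
        p = prior[state[id(tree.seed_node)]]
        for n in nodes:
            if n is not tree.seed_node:
                p *= P[id(n)][state[id(n.parent_node)], state[id(n)]]
        total += p
    return np.log(total)


class TestRateMatrix:
    def test_named_entries(self):
        m = cf.PairRateModel(1.5, 0.7, 2.0, 0.3, g_a=0.5, l_a=4.0, g_b=2.0, l_b=0.25)
        Q = build_rate_matrix(m)
        s = {x: i for i, x in enumerate(STATES)}
        assert Q[s["00"], s["10"]] == 1.5            # gain A
        assert Q[s["01"], s["11"]] == 1.5 * 0.5      # gain A while B present
        assert Q[s["10"], s["11"]] == 2.0 * 2.0      # gain B while A present
        assert Q[s["11"], s["10"]] == 0.3 * 0.25     # loss B while A present
        assert Q[s["00"], s["11"]] == 0 and Q[s["01"], s["10"]] == 0

    def test_zero_multiplier_vetoes_transition(self):
        Q = build_rate_matrix(cf.PairRateModel(g_a=0.0))
        s = {x: i for i, x in enumerate(STATES)}
        assert Q[s["01"], s["11"]] == 0.0

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            Q = build_rate_matrix(cf.PairRateModel(*rng.uniform(0.1, 5, 8)))
            assert np.allclose(Q.sum(axis=1), 0.0)

    def test_symmetric_model_has_uniform_stationary(self):
        Q = build_rate_matrix(cf.PairRateModel(1, 1, 1, 1))
        assert np.allclose(stationary_distribution(Q), 0.25)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            cf.PairRateModel(gain_a=0.0)


class TestTransitionMatrices:
    def test_rows_are_distributions(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            Q = build_rate_matrix(cf.PairRateModel(*rng.uniform(0.05, 8, 8)))
            P = _transition_matrices(Q, np.array([0.0, 0.01, 0.5, 3.0, 100.0]))
            assert (P >= 0).all()
            assert np.allclose(P.sum(axis=2), 1.0)
            assert np.allclose(P[0], np.eye(4), atol=1e-12)


class TestPruning:
    def test_single_tip_uniform_prior(self):
        tree = dendropy.Tree()
        tree.seed_node.taxon = tree.taxon_namespace.new_taxon("a")
        Q = build_rate_matrix(cf.PairRateModel())
        ll = cf.prune_likelihood(tree, {"a": "11"}, Q, root_prior="uniform")
        assert ll == pytest.approx(np.log(0.25))

    def test_long_branches_reach_stationary_limit(self):
        tree = cf.read_newick(None, data="(a:500,b:500);")
        m = cf.PairRateModel(1.2, 0.8, 0.5, 1.5)
        Q = build_rate_matrix(m)
        pi = stationary_distribution(Q)
        ll = cf.prune_likelihood(tree, {"a": "11", "b": "00"}, Q, root_prior="stationary")
        assert ll == pytest.approx(np.log(pi[3]) + np.log(pi[0]), abs=1e-6)

    def test_matches_enumeration_on_random_trees(self):
        rng = np.random.default_rng(5)
        for rep in range(20):
            n = int(rng.integers(2, 7))
            tree = cf.simulate_species_tree(n, seed=int(rng.integers(10_000)))
            Q = build_rate_matrix(cf.PairRateModel(*rng.uniform(0.1, 3.0, 8)))
            states = {t: int(rng.integers(4)) for t in cf.tip_labels(tree)}
            pi = stationary_distribution(Q)
            assert cf.prune_likelihood(tree, states, Q, root_prior=pi) == pytest.approx(
                brute_force_loglik(tree, states, Q, pi), abs=1e-9
            )

    def test_invariant_under_tip_dict_order(self, tree50):
        Q = build_rate_matrix(cf.PairRateModel(1, 0.5, 2, 0.7))
        states = {t: i % 4 for i, t in enumerate(cf.tip_labels(tree50))}
        rev = dict(reversed(states.items()))
        assert cf.prune_likelihood(tree50, states, Q) == cf.prune_likelihood(tree50, rev, Q)

    def test_missing_tip_state_rejected(self, tree50):
        Q = build_rate_matrix(cf.PairRateModel())
        with pytest.raises(ValueError, match="state"):
            cf.prune_likelihood(tree50, {"s01": "11"}, Q)


@pytest.fixture(scope="module")
def fitted(tree100):
    sim = cf.simulate_trait_pair(tree100, cf.PairRateModel(1.0, 0.5, 0.8, 0.6),
                                 root_state="10", seed=1)
    index = TreeIndex(tree100)
    dep = cf.fit_model(index, sim.matrix, "dependent", seed=0)
    indep = cf.fit_model(index, sim.matrix, "independent", seed=0)
    return dep, indep, sim


class TestFitting:
    def test_nesting(self, fitted):
        dep, indep, _ = fitted
        assert dep.log_likelihood >= indep.log_likelihood - 0.02

    def test_lrt_basics(self, fitted):
        dep, indep, _ = fitted
        res = cf.lrt_interaction(dep, indep)
        assert res.statistic >= 0 and res.df == 4 and 0 <= res.p_value <= 1

    def test_identical_fits_give_p_one(self, fitted):
        dep, indep, _ = fitted
        tied = cf.FitResult("dependent", dep.model, indep.log_likelihood, True,
                            1, data_key=indep.data_key)
        res = cf.lrt_interaction(tied, indep)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_different_data_rejected(self, fitted, tree100):
        dep, indep, _ = fitted
        other = cf.simulate_trait_pair(tree100, cf.PairRateModel(), seed=99)
        indep2 = cf.fit_model(tree100, other.matrix, "independent", seed=0)
        with pytest.raises(ValueError, match="different data"):
            cf.lrt_interaction(dep, indep2)

    def test_constant_trait_flagged(self, tree50):
        states = {t: "10" for t in cf.tip_labels(tree50)}
        fit = cf.fit_model(tree50, states, "independent", seed=0, n_restarts=2)
        assert fit.warnings  # both traits constant

    def test_lrt_invariant_under_trait_swap(self, tree100):
        sim = cf.simulate_trait_pair(
            tree100, cf.PairRateModel(1.0, 0.4, 0.5, 0.8, g_a=0.2, l_a=5, g_b=0.2, l_b=5),
            root_state="10", seed=3)
        swapped = cf.PresenceAbsenceMatrix(sim.matrix.df[["famB", "famA"]])
        r1 = interaction_test(tree100, sim.matrix, seed=0)
        r2 = interaction_test(tree100, swapped, seed=0)
        assert r1.lrt.statistic == pytest.approx(r2.lrt.statistic, abs=0.05)
        assert r1.sign == r2.sign


class TestInteractionSign:
    def make_fit(self, g, l):
        model = cf.PairRateModel(1, 1, 1, 1, g_a=g[0], l_a=l[0], g_b=g[1], l_b=l[1])
        return cf.FitResult("dependent", model, 0.0, True, 1)

    def test_complementary(self):
        assert cf.interaction_sign(self.make_fit((0.1, 0.1), (5, 5))) == "complementary"

    def test_correlated(self):
        assert cf.interaction_sign(self.make_fit((3, 3), (0.2, 0.2))) == "correlated"

    def test_mixed_is_none(self):
        assert cf.interaction_sign(self.make_fit((2, 0.5), (1, 1))) == "none"
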