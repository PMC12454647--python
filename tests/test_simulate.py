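import numpy as np
import pytest

import convfuse as cf
from convfuse.coevolution import build_rate_matrix
from convfuse.records import PresenceAbsenceMatrix
from convfuse.simulate import PlantedPair, random_protein


def tree_height(tree):
    heights = []
    for leaf in tree.leaf_node_iter():
        h, node = 0.0, leaf
        while node.parent_node is not None:
            h += node.edge.length or 0.0
            node = node.parent_node
        heights.append(h)
    return np.mean(heights)


class TestSpeciesTree:
    def test_two_tips_is_cherry(self):
        tree = cf.simulate_species_tree(2, birth_rate=1.0, seed=1)
        assert len(cf.tip_labels(tree)) == 2
        assert len(tree.seed_node.child_nodes()) == 2

    def test_determinism(self):
        a = cf.simulate_species_tree(50, seed=7)
        b = cf.simulate_species_tree(50, seed=7)
        assert cf.newick_string(a) == cf.newick_string(b)

    def test_positive_branch_lengths(self, tree50):
        for edge in tree50.preorder_edge_iter():
            if edge.head_node.parent_node is not None:
                assert edge.length > 0

    def test_yule_depth_matches_closed_form(self):
        # E[depth] = sum_{k=2..n} 1/(k*birth) for the pure-birth sampler
        n, birth, reps = 8, 2.0, 100
        expected = sum(1.0 / (k * birth) for k in range(2, n + 1))
        depths = [tree_height(cf.simulate_species_tree(n, birth, 0.0, seed=s))
                  for s in range(reps)]
        se = np.std(depths) / np.sqrt(reps)
        assert abs(np.mean(depths) - expected) < 3 * se + 1e-9

    def test_death_rate_still_reaches_tip_count(self):
        tree = cf.simulate_species_tree(20, birth_rate=1.0, death_rate=0.4, seed=3)
        assert len(cf.tip_labels(tree)) == 20

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            cf.simulate_species_tree(5, birth_rate=0.5, death_rate=0.5, seed=0)
        with pytest.raises(ValueError):
            cf.simulate_species_tree(1, seed=0)


class TestTraitPair:
    def test_no_loss_from_full_root_is_absorbing(self, tree50):
        model = cf.PairRateModel(1.0, 1e-9, 1.0, 1e-9)
        sim = cf.simulate_trait_pair(tree50, model, root_state="11", seed=2)
        assert (sim.matrix.values == 1).all()

    def test_independence_when_multipliers_one(self, tree100):
        # with no interaction, P(both present) factorizes over the marginals
        model = cf.PairRateModel(1.0, 0.8, 0.6, 0.9)
        reps = 400
        both = np.empty(reps)
        a = np.empty(reps)
        b = np.empty(reps)
        for i in range(reps):
            sim = cf.simulate_trait_pair(tree100, model, root_state="00", seed=5000 + i)
            v = sim.matrix.values
            a[i] = v[:, 0].mean()
            b[i] = v[:, 1].mean()
            both[i] = (v[:, 0] & v[:, 1]).mean()
        diff = both - a * b
        se = diff.std(ddof=1) / np.sqrt(reps)
        assert abs(diff.mean()) < 3 * se + 1e-9

    def test_strong_negative_interaction_excludes_cooccurrence(self, tree100):
        model = cf.PairRateModel(1.0, 0.2, 1.0, 0.2, g_a=0.0, l_a=20.0, g_b=0.0, l_b=20.0)
        total_both = 0
        for s in range(20):
            sim = cf.simulate_trait_pair(tree100, model, root_state="10", seed=s)
            v = sim.matrix.values
            total_both += int((v[:, 0] & v[:, 1]).sum())
        assert total_both == 0  # veto multipliers forbid ever fixing 11 at tips

    def test_rows_match_tree_tips(self, tree50):
        sim = cf.simulate_trait_pair(tree50, cf.PairRateModel(), seed=0)
        assert sim.matrix.species == cf.tip_labels(tree50)


class TestDomainFamily:
    def test_zero_rate_keeps_root_sequence(self, tree50):
        root = random_protein(60, np.random.default_rng(0))
        recs = cf.simulate_domain_family(tree50, root, substitution_rate=0.0, seed=1)
        assert all(r.sequence == root for r in recs)

    def test_determinism(self, tree50):
        root = random_protein(40, np.random.default_rng(0))
        a = cf.simulate_domain_family(tree50, root, 0.5, seed=9)
        b = cf.simulate_domain_family(tree50, root, 0.5, seed=9)
        assert [r.sequence for r in a] == [r.sequence for r in b]

    @pytest.mark.parametrize("d", [0.2, 1.0, 2.5])
    def test_identity_decay_matches_closed_form(self, d):
        # two tips at path distance d: E[identity] = 1/20 + 19/20 exp(-20d/19)
        newick = f"(a:{d / 2},b:{d / 2});"
        tree = cf.read_newick(None, data=newick)
        L, reps = 200, 60
        expected = 1 / 20 + (19 / 20) * np.exp(-20 * d / 19)
        idents = []
        for s in range(reps):
            ra, rb = cf.simulate_domain_family(tree, random_protein(L, np.random.default_rng(s)),
                                               1.0, seed=s)
            idents.append(np.mean([x == y for x, y in zip(ra.sequence, rb.sequence)]))
        se = np.std(idents, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(idents) - expected) < 3 * se + 0.005

    def test_invariant_sites_are_frozen(self, tree50):
        root = random_protein(50, np.random.default_rng(3))
        frozen = np.arange(0, 50, 5)
        recs = cf.simulate_domain_family(tree50, root, 5.0, seed=2, invariant_sites=frozen)
        for r in recs:
            assert all(r.sequence[i] == root[i] for i in frozen)


class TestFusion:
    def make_pair(self):
        a = [cf.ProteinRecord("n|s1", "A" * 480, species_id="s1")]
        b = [cf.ProteinRecord("c|s1", "W" * 370, species_id="s1")]
        return a, b

    def test_length_additivity_and_architecture(self):
        a, b = self.make_pair()
        fused = cf.make_fusion_family(a, b, linker="G" * 10, family="fam")
        assert fused[0].length == 480 + 10 + 370
        assert fused[0].architecture == ["ALDH", "ADH"]

    def test_reversed_order(self):
        a, b = self.make_pair()
        fused = cf.make_fusion_family(a, b, linker="G", order="reversed")
        assert fused[0].architecture == ["ADH", "ALDH"]
        assert fused[0].sequence.startswith("W")

    def test_unpaired_species_error(self):
        a, _ = self.make_pair()
        b = [cf.ProteinRecord("c|s2", "W" * 10, species_id="s2")]
        with pytest.raises(ValueError, match="s1"):
            cf.make_fusion_family(a, b)

    def test_fused_protein_matches_donor_over_first_segment(self, tree50):
        root_n = random_protein(120, np.random.default_rng(1))
        root_c = random_protein(90, np.random.default_rng(2))
        fam_n = cf.simulate_domain_family(tree50, root_n, 0.05, seed=4)
        fam_c = cf.simulate_domain_family(tree50, root_c, 0.05, seed=5)
        fused = cf.make_fusion_family(fam_n, fam_c, linker="GGS")
        donor = fam_n[0]
        hit = cf.align_pair(donor, fused[0], mode="glocal")
        assert hit.identity == pytest.approx(100.0)
        assert hit.target_coverage == pytest.approx(100 * 120 / fused[0].length, abs=0.5)


class TestGenomes:
    def presence(self, n, fams=("famA", "famB")):
        values = np.ones((n, len(fams)), dtype=int)
        return PresenceAbsenceMatrix.from_arrays([f"s{i}" for i in range(n)], list(fams), values)

    def test_forced_adjacency_is_consecutive_same_strand(self):
        genomes, truth = cf.assemble_genomes(
            self.presence(5), [PlantedPair("famA", "famB", 1.0, 0)], genome_length=12, seed=0)
        for g in genomes:
            pairs = cf.find_adjacent_pairs(g, "famA", "famB")
            assert len(pairs) == 1
            a, b, gap = pairs[0]
            assert gap == 0 and a.strand == b.strand
        assert all(t.adjacent for t in truth)

    def test_zero_probability_means_no_adjacency(self):
        genomes, truth = cf.assemble_genomes(
            self.presence(10), [PlantedPair("famA", "famB", 0.0, 3)], genome_length=12, seed=1)
        for g in genomes:
            assert cf.find_adjacent_pairs(g, "famA", "famB") == []
        assert not any(t.adjacent for t in truth)

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="genome_length"):
            cf.assemble_genomes(self.presence(2), [PlantedPair("famA", "famB", 1.0, 5)],
                                genome_length=1, seed=0)

    def test_unknown_family_error(self):
        with pytest.raises(ValueError, match="famX"):
            cf.assemble_genomes(self.presence(2), [PlantedPair("famX", "famB", 0.5, 1)],
                                genome_length=10, seed=0)

    def test_filler_labels_unique_within_genome(self):
        genomes, _ = cf.assemble_genomes(
            self.presence(3), [PlantedPair("famA", "famB", 0.5, 2)], genome_length=15, seed=2)
        for g in genomes:
            labels = [l.ortholog for l in g.loci]
            assert len(labels) == len(set(labels))


class TestHabitat:
    def test_noise_free_effect_is_exact(self):
        presence = {f"s{i}": i % 2 for i in range(10)}
        hm = cf.simulate_habitat_matrix(presence, ["e1", "e2"], "e2",
                                        effect_size=0.4, noise_sd=0.0, seed=0)
        report = cf.enrichment_score(hm, presence)
        assert report.scores["e2"] == pytest.approx(0.4)
        assert report.scores["e1"] == pytest.approx(0.0)

    def test_effect_recovered_within_error(self):
        presence = {f"s{i}": int(i < 100) for i in range(200)}
        hm = cf.simulate_habitat_matrix(presence, ["e1", "e2"], "e1",
                                        effect_size=0.4, noise_sd=0.1, seed=3)
        report = cf.enrichment_score(hm, presence)
        se = 0.1 * np.sqrt(1 / 100 + 1 / 100)
        assert abs(report.scores["e1"] - 0.4) < 3 * se
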