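import numpy as np
import pytest

from phylosieve.models import poisson_model
from phylosieve.recode import recode
from phylosieve.reconcile import DTLRates, SpeciesTree, extinction_probs
from phylosieve.synthetic import (
    ArtifactScenario, HeterogeneitySpec, SimulationError, artifact_scenario,
    simulate_alignment, simulate_gene_family, simulate_species_tree,
    within_bin_biased_frequencies,
)
from phylosieve.trees import parse_newick, write_newick


class TestSpeciesTrees:
    def test_two_leaves_is_a_cherry(self):
        tree = simulate_species_tree(2, seed=0)
        assert len(tree.leaves()) == 2
        assert len(tree.root.children) == 2

    @pytest.mark.parametrize("n", [2, 5, 16])
    def test_leaf_count_matches_request(self, n):
        assert len(simulate_species_tree(n, seed=3).leaves()) == n

    def test_same_seed_identical_newick(self):
        assert write_newick(simulate_species_tree(12, seed=9)) == \
            write_newick(simulate_species_tree(12, seed=9))

    def test_single_leaf_rejected(self):
        with pytest.raises(SimulationError):
            simulate_species_tree(1)


class TestGeneFamilies:
    def test_null_process_gives_one_copy_per_leaf(self, toy_species_tree):
        stree = SpeciesTree(parse_newick("((A,B),C);"))
        h = simulate_gene_family(stree, DTLRates(0, 0, 0), seed=1,
                                 origin=stree.root_index)
        assert h.observed_counts == {"A": 1, "B": 1, "C": 1}
        assert h.n_redraws == 0

    def test_sampling_failure_matches_binomial_expectation(self):
        stree = SpeciesTree(parse_newick("(A,B);"), {"A": 0.3, "B": 0.3})
        rates = DTLRates(0, 0, 0)
        observed = 0
        n = 4000
        for i in range(n):
            h = simulate_gene_family(stree, rates, seed=i, origin=stree.root_index,
                                     condition_on_observation=False)
            observed += h.observed_counts.get("A", 0)
        p = observed / n
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(p - 0.7) < 3 * se

    def test_survival_frequency_matches_extinction_probabilities(self,
                                                                 toy_species_tree):
        rates = DTLRates(0.05, 0.02, 0.2)
        E = extinction_probs(toy_species_tree, rates)
        survived = np.zeros(toy_species_tree.n_branches)
        total = np.zeros(toy_species_tree.n_branches)
        n = 15_000
        for i in range(n):
            h = simulate_gene_family(toy_species_tree, rates, seed=i,
                                     condition_on_observation=False)
            total[h.origin] += 1
            survived[h.origin] += bool(h.observed_counts)
        freq = 1 - survived / total
        se = np.sqrt(np.maximum(freq * (1 - freq), 1e-6) / total)
        assert np.all(np.abs(freq - E) < 3 * se + 1e-9)

    def test_replaying_events_reproduces_recorded_copies(self, toy_species_tree):
        rates = DTLRates(0.1, 0.05, 0.2)
        for seed in range(30):
            h = simulate_gene_family(toy_species_tree, rates, seed=seed)
            replayed = np.zeros(toy_species_tree.n_branches)
            for ev in h.events:
                if ev[0] in ("S", "C", "U"):
                    replayed[ev[1]] += 1
            assert np.array_equal(replayed, h.true_copies)

    def test_observed_never_exceeds_true_leaf_copies(self, toy_species_tree):
        rates = DTLRates(0.2, 0.1, 0.1)
        for seed in range(20):
            h = simulate_gene_family(toy_species_tree, rates, seed=seed)
            for genome, count in h.observed_counts.items():
                e = toy_species_tree.leaf_index[genome]
                assert count <= h.true_copies[e]

    def test_runaway_rates_abort(self):
        stree = SpeciesTree(parse_newick("(A,B);"))
        with pytest.raises(SimulationError, match="runaway"):
            simulate_gene_family(stree, DTLRates(9.0, 0.0, 0.0), seed=0,
                                 max_events=5000)


class TestAlignments:
    def test_zero_length_branches_give_identical_taxa(self):
        tree = parse_newick("((A:0,B:0):0,C:0);")
        spec = HeterogeneitySpec(alpha=1.0, n_rate_classes=1)
        aln, _, _ = simulate_alignment(tree, poisson_model(4), spec, 100, seed=0)
        assert aln.row("A") == aln.row("B") == aln.row("C")

    def test_overridden_lineage_converges_to_its_equilibrium(self):
        pi = within_bin_biased_frequencies(0.9)
        tree = parse_newick("(A:8.0,B:0.1);")
        spec = HeterogeneitySpec(alpha=1.0, n_rate_classes=1,
                                 frequency_overrides={"A": pi})
        aln, _, _ = simulate_alignment(tree, poisson_model(20), spec, 10_000,
                                       seed=2)
        from phylosieve.composition import taxon_composition
        table = taxon_composition(aln)
        freq = table.frequencies[aln.taxa.index("A")]
        se = np.sqrt(pi * (1 - pi) / 10_000)
        assert np.all(np.abs(freq - pi) < 3 * se + 5e-3)

    def test_alpha_recovered_by_rate_estimation(self):
        from phylosieve.site_rates import estimate_alpha
        tree = simulate_species_tree(16, seed=6)
        spec = HeterogeneitySpec(alpha=0.5, n_rate_classes=8)
        aln, _, _ = simulate_alignment(tree, poisson_model(4), spec, 2000, seed=6)
        assert abs(estimate_alpha(aln, tree, poisson_model(4)) - 0.5) < 0.2

    def test_invalid_length_rejected(self):
        tree = parse_newick("(A:0.1,B:0.1);")
        with pytest.raises(SimulationError):
            simulate_alignment(tree, poisson_model(4),
                               HeterogeneitySpec(alpha=1.0), 0)


class TestWithinBinBias:
    def test_sums_to_one_and_preserves_bin_mass(self):
        pi = within_bin_biased_frequencies(0.8)
        assert pi.sum() == pytest.approx(1.0)
        from phylosieve.alignment import AA20
        from phylosieve.recode import SR4_BINS
        for residues in SR4_BINS.values():
            mass = sum(pi[AA20.index(r)] for r in residues)
            assert mass == pytest.approx(len(residues) / 20)

    def test_bias_invisible_after_recoding(self):
        """The same number of symbols per recoded state before and after
        the within-bin shift: recoding removes the convergent signal."""
        pi = within_bin_biased_frequencies(0.9)
        tree = parse_newick("(A:5.0,B:5.0);")
        spec = HeterogeneitySpec(alpha=1.0, n_rate_classes=1,
                                 frequency_overrides={"A": pi, "B": pi})
        aln, _, _ = simulate_alignment(tree, poisson_model(20), spec, 8000, seed=4)
        recoded = recode(aln)
        from phylosieve.composition import taxon_composition
        # recoded compositions match the neutral bin masses (6,4,5,5)/20
        freqs = taxon_composition(recoded).frequencies
        bin_mass = np.array([0.3, 0.2, 0.25, 0.25])
        assert np.all(np.abs(freqs - bin_mass) < 0.03)


class TestScenario:
    def test_same_seed_identical_bundle(self):
        a = artifact_scenario(seed=3, L=120)
        b = artifact_scenario(seed=3, L=120)
        assert np.array_equal(a.alignment.data, b.alignment.data)
        assert write_newick(a.true_tree) == write_newick(b.true_tree)

    def test_bundle_is_fully_labelled(self):
        scen = artifact_scenario(seed=1, L=60)
        assert isinstance(scen, ArtifactScenario)
        assert len(scen.true_tree.leaves()) == 20
        assert set(scen.query_taxa) <= set(scen.alignment.taxa)
        assert scen.true_edge in scen.candidates
        assert scen.attractor_edge in scen.candidates
        assert not set(scen.query_taxa) & set(scen.backbone.leaf_labels())
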