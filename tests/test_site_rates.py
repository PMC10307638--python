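import numpy as np
import pytest
from oracles import brute_force_percat_site_lik
from scipy.stats import spearmanr

from phylosieve.alignment import Alignment
from phylosieve.models import discrete_gamma_rates, poisson_model
from phylosieve.recode import sr4_scheme
from phylosieve.site_rates import (SiteRateError, SiteRateProfile,
                                   categorize_deciles, estimate_alpha,
                                   fsr_series, posterior_site_rates, treat)
from phylosieve.synthetic import (HeterogeneitySpec, simulate_alignment,
                                  simulate_species_tree)
from phylosieve.trees import parse_newick


def _profile(rates):
    rates = np.asarray(rates, dtype=float)
    return SiteRateProfile(alpha=1.0, k=4, category_rates=np.ones(4),
                           site_rates=rates)


def test_discrete_gamma_categories_average_to_one():
    for alpha in (0.1, 0.5, 2.0, 20.0):
        rates = discrete_gamma_rates(alpha, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(rates) > 0)


class TestAlphaEstimation:
    def test_recovers_simulated_shape(self):
        tree = simulate_species_tree(32, seed=5)
        spec = HeterogeneitySpec(alpha=0.5, n_rate_classes=8)
        aln, _, _ = simulate_alignment(tree, poisson_model(4), spec, 2000, seed=5)
        alpha = estimate_alpha(aln, tree, poisson_model(4))
        assert abs(alpha - 0.5) < 0.2

    def test_rate_homogeneous_data_pushes_alpha_to_upper_bound(self):
        tree = simulate_species_tree(16, seed=2)
        spec = HeterogeneitySpec(alpha=1.0, n_rate_classes=1)
        aln, _, _ = simulate_alignment(tree, poisson_model(4), spec, 1500, seed=2)
        assert estimate_alpha(aln, tree, poisson_model(4)) >= 10.0

    def test_constant_alignment_rejected(self):
        aln = Alignment(["A", "B"], np.array([["A", "A"], ["A", "A"]]), "SR4")
        with pytest.raises(SiteRateError, match="alpha undefined"):
            estimate_alpha(aln, parse_newick("(A:0.1,B:0.1);"), poisson_model(4))


class TestPosteriorRates:
    def test_matches_direct_category_enumeration_on_toy(self, quartet_tree):
        rng = np.random.default_rng(0)
        data = rng.choice(list("ACGT"), size=(4, 5))
        aln = Alignment(list("ABCD"), data, "SR4")
        model = poisson_model(4)
        alpha, k = 0.6, 4
        profile = posterior_site_rates(aln, quartet_tree, model, alpha, k)
        liks = brute_force_percat_site_lik(aln, quartet_tree,
                                           model.with_alpha(alpha, k))
        rates = discrete_gamma_rates(alpha, k)
        want = (rates[:, None] * liks).sum(0) / liks.sum(0)
        assert np.allclose(profile.site_rates, want, atol=1e-10)

    def test_invariant_column_slower_than_alignment_mean(self, quartet_tree):
        rows = {"A": "AAAAC", "B": "ACGTC", "C": "AGTCC", "D": "ATACC"}
        aln = Alignment(list(rows), np.array([list(v) for v in rows.values()]), "SR4")
        profile = posterior_site_rates(aln, quartet_tree, poisson_model(4), 0.5)
        # column 4 is constant; column 0 nearly so
        assert profile.site_rates[4] < profile.site_rates.mean()

    def test_symmetric_columns_get_equal_rates(self):
        tree = parse_newick("((A:0.3,B:0.3):0.2,(C:0.3,D:0.3):0.2);")
        rows = {"A": "AC", "B": "CA", "C": "GT", "D": "TG"}
        aln = Alignment(list(rows), np.array([list(v) for v in rows.values()]), "SR4")
        profile = posterior_site_rates(aln, tree, poisson_model(4), 0.7)
        assert profile.site_rates[0] == pytest.approx(profile.site_rates[1], abs=1e-10)


class TestDeciles:
    def test_even_split_for_l20(self):
        p = categorize_deciles(_profile(np.linspace(2, 0.1, 20)))
        assert np.bincount(p.decile)[1:].tolist() == [2] * 10

    def test_l23_sizes_differ_by_at_most_one(self):
        p = categorize_deciles(_profile(np.linspace(2, 0.1, 23)))
        sizes = np.bincount(p.decile)[1:]
        assert sorted(sizes.tolist(), reverse=True) == [3, 3, 3] + [2] * 7

    def test_ties_broken_by_column_index(self):
        p = categorize_deciles(_profile(np.ones(20)))
        assert p.decile.tolist() == sorted(p.decile.tolist())

    def test_too_short_alignment_rejected(self):
        with pytest.raises(SiteRateError):
            categorize_deciles(_profile(np.ones(9)))


class TestRemovalSeries:
    def _aln(self, L):
        rng = np.random.default_rng(1)
        return Alignment(["A", "B"], rng.choice(list("ACGT"), size=(2, L)), "SR4")

    def test_floor_rule(self):
        aln = self._aln(20)
        series = fsr_series(aln, _profile(np.linspace(2, 0.1, 20)), fractions=(0.1,))
        assert len(series.masks[0.1]) == 18

    def test_masks_strictly_nested_across_full_ladder(self):
        rng = np.random.default_rng(3)
        aln = self._aln(57)
        series = fsr_series(aln, _profile(rng.uniform(0.1, 3.0, 57)))
        fr = sorted(series.fractions)
        for f1, f2 in zip(fr, fr[1:]):
            assert set(series.masks[f2]) < set(series.masks[f1])

    def test_fraction_outside_unit_interval_rejected(self):
        aln = self._aln(20)
        with pytest.raises(SiteRateError):
            fsr_series(aln, _profile(np.ones(20)), fractions=(1.5,))

    def test_removed_sites_are_faster_on_average_than_retained(self):
        tree = simulate_species_tree(16, seed=9)
        spec = HeterogeneitySpec(alpha=0.5, n_rate_classes=8)
        aln, true_rates, _ = simulate_alignment(tree, poisson_model(4), spec,
                                                600, seed=9)
        alpha = estimate_alpha(aln, tree, poisson_model(4))
        profile = posterior_site_rates(aln, tree, poisson_model(4), alpha)
        series = fsr_series(aln, profile, fractions=(0.3,))
        retained = series.masks[0.3]
        removed = np.setdiff1d(np.arange(aln.n_cols), retained)
        assert true_rates[removed].mean() > true_rates[retained].mean()


class TestCombinedTreatment:
    def test_identity_when_no_fraction_and_no_scheme(self, small_aa_alignment):
        tree = parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        out = treat(small_aa_alignment, tree, poisson_model(20), 0.0)
        assert np.array_equal(out.data, small_aa_alignment.data)

    def test_composition_of_removal_and_recoding(self):
        tree = simulate_species_tree(8, seed=4)
        spec = HeterogeneitySpec(alpha=0.8, n_rate_classes=4)
        aln, _, _ = simulate_alignment(tree, poisson_model(20), spec, 50, seed=4)
        model = poisson_model(20)
        alpha = estimate_alpha(aln, tree, model)
        profile = posterior_site_rates(aln, tree, model, alpha)
        combined = treat(aln, tree, model, 0.2, sr4_scheme(), profile=profile)
        assert combined.n_cols == 50 - 10
        assert combined.alphabet == "SR4"
        # definitional equality with manual chaining
        from phylosieve.recode import recode
        series = fsr_series(aln, profile, fractions=(0.2,))
        manual = recode(aln.take_columns(series.masks[0.2]), sr4_scheme())
        assert np.array_equal(combined.data, manual.data)

    def test_recoded_input_rejected(self, small_aa_alignment):
        tree = parse_newick("((A:0.2,B:0.2):0.1,(C:0.2,D:0.2):0.1);")
        from phylosieve.recode import recode
        with pytest.raises(SiteRateError):
            treat(recode(small_aa_alignment), tree, poisson_model(20), 0.1)
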