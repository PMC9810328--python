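"""Synthetic-data generators: determinism and planted ground truth."""

import math

import numpy as np
import pytest

from oncoclade import phylo, rbhb
from oncoclade.simulate import (
    DuplicationParams,
    PhenotypeParams,
    PrevalenceParams,
    PslParams,
    TraitParams,
    TreeParams,
    simulate_duplications,
    simulate_phenotypes,
    simulate_prevalence,
    simulate_psl,
    simulate_traits,
    simulate_tree,
)


class TestTree:
    def test_pure_birth_is_ultrametric(self):
        tree = simulate_tree(TreeParams(n_tips=20, death=0.0), seed=1)
        ages = tree.tip_ages()
        assert len(tree.tips()) == 20
        assert all(a <= 1e-5 for a in ages.values())

    def test_requested_extant_tip_count(self):
        tree = simulate_tree(TreeParams(n_tips=40), seed=2)
        extant = [a for a in tree.tip_ages().values() if a <= 1e-5]
        assert len(extant) == 40

    def test_extinct_fraction_retained(self):
        tree = simulate_tree(TreeParams(n_tips=40, death=0.08,
                                        extinct_tip_fraction=0.5), seed=3)
        fossil = [a for a in tree.tip_ages().values() if a > 1e-5]
        assert len(fossil) >= 1

    def test_same_seed_identical(self):
        a = simulate_tree(TreeParams(n_tips=15), seed=9)
        b = simulate_tree(TreeParams(n_tips=15), seed=9)
        assert phylo.write_newick(a) == phylo.write_newick(b)


class TestTraits:
    def test_zero_rate_constant_trait(self, four_taxon_tree):
        params = TraitParams(sigma2=0.0, jump_rate=0.0, lifespan_noise_sigma2=0.0)
        table, truth = simulate_traits(four_taxon_tree, params, seed=0)
        assert np.allclose(table["mass_g"], math.exp(params.root_ln_mass))

    def test_increment_variance_matches_rate(self):
        # single 50 My branch: Var(tip - root) ~ sigma2 * T
        tree = phylo.read_newick("(A:50);")
        params = TraitParams(sigma2=0.04, jump_rate=0.0)
        increments = []
        for seed in range(400):
            _, truth = simulate_traits(tree, params, seed)
            increments.append(truth["A"] - truth[tree.root.label])
        var = np.var(increments)
        assert var == pytest.approx(0.04 * 50, rel=0.25)

    def test_flat_allometry_decouples_lifespan(self, four_taxon_tree):
        params = TraitParams(sigma2=0.5, jump_rate=0.0, beta2=0.0,
                             lifespan_noise_sigma2=0.0)
        table, _ = simulate_traits(four_taxon_tree, params, seed=4)
        assert np.allclose(table["lifespan_yr"], math.exp(params.beta1))

    def test_same_seed_identical(self, four_taxon_tree):
        a, ta = simulate_traits(four_taxon_tree, TraitParams(), seed=7)
        b, tb = simulate_traits(four_taxon_tree, TraitParams(), seed=7)
        assert a.equals(b) and ta == tb


class TestDuplications:
    def test_zero_rates_all_zero_matrix(self, four_taxon_tree):
        params = DuplicationParams(n_genes=50, base_gain=0.0, burst_gain=0.0,
                                   loss=0.0, burst_branches=["A"])
        matrix, gains, _ = simulate_duplications(four_taxon_tree, params, seed=0)
        assert matrix.to_numpy().sum() == 0
        assert all(not g for g in gains.values())

    def test_half_life_burst_duplicates_half_the_genes(self):
        # gain rate * T = ln 2 on the burst branch, no loss:
        # P(gain) = 1 - exp(-ln 2) = 1/2
        tree = phylo.read_newick("((A:1,B:1)X:10,(C:1,D:1):10);")
        lam = math.log(2) / 10
        params = DuplicationParams(n_genes=4000, base_gain=0.0, burst_gain=lam,
                                   loss=0.0, burst_branches=["X"])
        matrix, gains, _ = simulate_duplications(tree, params, seed=1)
        frac = np.mean([bool(b) for b in gains.values()])
        se = math.sqrt(0.25 / 4000)
        assert frac == pytest.approx(0.5, abs=4 * se)
        # gained genes are duplicated in the whole subtree
        gained = [g for g, b in gains.items() if b]
        assert np.all(matrix.loc[gained, ["A", "B"]].to_numpy() == 1)

    def test_event_counts_match_expectation(self):
        tree = phylo.read_newick("((A:1,B:1)X:5,(C:1,D:1):5);")
        lam = 0.05
        params = DuplicationParams(n_genes=3000, base_gain=0.0, burst_gain=lam,
                                   loss=0.0, burst_branches=["X"])
        _, gains, _ = simulate_duplications(tree, params, seed=2)
        n_events = sum(len(b) for b in gains.values())
        expected = 3000 * (1 - math.exp(-lam * 5))
        sd = math.sqrt(3000 * (1 - math.exp(-lam * 5)) * math.exp(-lam * 5))
        assert abs(n_events - expected) < 4 * sd


class TestPsl:
    def test_single_copy_full_coverage(self):
        bundle = simulate_psl(
            PslParams(n_genes=10, fragmentation_prob=0.0,
                      copy_number_probs={1: 1.0}, mismatch_rate=0.0),
            seed=0,
        )
        hits, _ = rbhb.reciprocal_best_hits(
            bundle["forward"], bundle["reciprocal"], bundle["isoform_to_gene"]
        )
        by_iso = {}
        for h in hits:
            by_iso.setdefault(h.query_isoform, []).append(h)
        for iso, iso_hits in by_iso.items():
            res = rbhb.ecnc(bundle["query_sizes"][iso], iso_hits, iso)
            assert res.ecnc == pytest.approx(1.0)
            assert len(iso_hits) == 1

    def test_two_copies_give_ecnc_two(self):
        bundle = simulate_psl(
            PslParams(n_genes=10, fragmentation_prob=0.0,
                      copy_number_probs={2: 1.0}),
            seed=1,
        )
        hits, _ = rbhb.reciprocal_best_hits(
            bundle["forward"], bundle["reciprocal"], bundle["isoform_to_gene"]
        )
        by_iso = {}
        for h in hits:
            by_iso.setdefault(h.query_isoform, []).append(h)
        for iso, iso_hits in by_iso.items():
            res = rbhb.ecnc(bundle["query_sizes"][iso], iso_hits, iso)
            assert res.ecnc == pytest.approx(2.0)

    def test_fragmented_single_copy_not_inflated(self):
        # hit count doubles but coverage-corrected copy number stays 1
        bundle = simulate_psl(
            PslParams(n_genes=10, fragmentation_prob=1.0,
                      copy_number_probs={1: 1.0}),
            seed=2,
        )
        hits, _ = rbhb.reciprocal_best_hits(
            bundle["forward"], bundle["reciprocal"], bundle["isoform_to_gene"]
        )
        by_iso = {}
        for h in hits:
            by_iso.setdefault(h.query_isoform, []).append(h)
        for iso, iso_hits in by_iso.items():
            res = rbhb.ecnc(bundle["query_sizes"][iso], iso_hits, iso)
            assert len(iso_hits) == 2
            assert res.ecnc == pytest.approx(1.0)

    def test_emitted_records_validate_and_round_trip(self, tmp_path):
        bundle = simulate_psl(PslParams(n_genes=15), seed=3)
        for rec in bundle["forward"] + bundle["reciprocal"]:
            rec.validate()
        path = tmp_path / "fwd.psl"
        rbhb.write_psl(bundle["forward"], path)
        assert rbhb.parse_psl(path) == bundle["forward"]


class TestPrevalencePhenotypes:
    def test_zero_prevalence_zero_cases(self):
        records, _ = simulate_prevalence(
            PrevalenceParams(taxa=[("t", 0.0, 500)]), seed=0
        )
        assert records[0].x == 0

    def test_large_sample_matches_truth(self):
        records, truth = simulate_prevalence(
            PrevalenceParams(taxa=[("t", 0.2, 20_000)]), seed=1
        )
        assert records[0].x / records[0].n == pytest.approx(0.2, abs=0.02)

    def test_same_seed_identical_tables(self):
        a, _ = simulate_prevalence(PrevalenceParams(), seed=5)
        b, _ = simulate_prevalence(PrevalenceParams(), seed=5)
        assert [(r.taxon, r.n, r.x) for r in a] == [(r.taxon, r.n, r.x) for r in b]

    def test_phenotype_clade_shift(self):
        groups, truth = simulate_phenotypes(PhenotypeParams(), seed=2)
        assert np.median(groups["sloths"]) > np.median(groups["mammals"])

    def test_phenotype_determinism(self):
        a, _ = simulate_phenotypes(PhenotypeParams(), seed=3)
        b, _ = simulate_phenotypes(PhenotypeParams(), seed=3)
        for clade in a:
            assert np.allclose(a[clade], b[clade])
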