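"""Two-state likelihoods, marginal reconstruction, duplication calling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from oncoclade import copy_number_asr as cn
from oncoclade import phylo, simulate

from conftest import random_tree


def enumeration_oracle(tree, observed, model):
    """Likelihood and marginals by summing over all internal-state maps."""
    internal = [n for n in tree.preorder() if not n.is_tip]
    tips = tree.tips()
    total = 0.0
    node_mass = {n.label: np.zeros(2) for n in tree.preorder()}
    for assign in itertools.product([0, 1], repeat=len(internal)):
        states = {n.label: s for n, s in zip(internal, assign)}
        weight_sets = []
        # tips may be observed or missing: sum over missing tips too
        missing = [t for t in tips if observed.get(t.label) is None]
        for miss_assign in itertools.product([0, 1], repeat=len(missing)):
            st = dict(states)
            for t in tips:
                if observed.get(t.label) is None:
                    st[t.label] = miss_assign[missing.index(t)]
                else:
                    st[t.label] = observed[t.label]
            p = model.pi[st[tree.root.label]]
            for n in tree.preorder():
                if n is tree.root:
                    continue
                P = model.transition_matrix(n.branch_length)
                p *= P[st[n.parent.label], st[n.label]]
            total += p
            for n in tree.preorder():
                node_mass[n.label][st[n.label]] += p
    marginals = {lab: mass[1] / total for lab, mass in node_mass.items()}
    return math.log(total), marginals


class TestLikelihood:
    def test_single_tip_reduces_to_stationary_frequency(self):
        tree = phylo.read_newick("(A:5);")
        model = cn.TwoStateModel(0.3, 0.7)
        ll = cn.likelihood({"A": 1}, tree, model)
        assert ll == pytest.approx(math.log(model.pi[1]), abs=1e-12)

    def test_all_missing_likelihood_one(self, four_taxon_tree):
        model = cn.TwoStateModel(0.2, 0.4)
        ll = cn.likelihood({}, four_taxon_tree, model)
        assert ll == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_on_small_trees(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(seed, n_tips=int(rng.integers(3, 7)))
        model = cn.TwoStateModel(float(rng.uniform(0.05, 1.0)),
                                 float(rng.uniform(0.05, 1.0)))
        observed = {
            t: (int(rng.integers(0, 2)) if rng.uniform() > 0.2 else None)
            for t in tree.tip_labels()
        }
        ll = cn.likelihood({k: v for k, v in observed.items() if v is not None},
                           tree, model)
        expected, _ = enumeration_oracle(tree, observed, model)
        assert ll == pytest.approx(expected, abs=1e-10)


class TestMarginalAsr:
    def test_symmetric_cherry_is_maximally_uncertain(self):
        tree = phylo.read_newick("(A:1,B:1);")
        model = cn.TwoStateModel(0.5, 0.5)
        mat = pd.DataFrame([[0, 1]], index=["g"], columns=["A", "B"])
        rec = cn.marginal_asr(mat, tree, model)
        assert rec.posterior("g", tree.root.label) == pytest.approx(0.5)

    def test_observed_tips_have_degenerate_posteriors(self, four_taxon_tree):
        model = cn.TwoStateModel(0.2, 0.3)
        mat = pd.DataFrame([[0, 1, 0, 1]], index=["g"], columns=list("ABCD"))
        rec = cn.marginal_asr(mat, four_taxon_tree, model)
        assert rec.posterior("g", "A") == pytest.approx(0.0)
        assert rec.posterior("g", "B") == pytest.approx(1.0)

    def test_all_zero_tips_favour_zero_everywhere(self, four_taxon_tree):
        model = cn.TwoStateModel(0.05, 0.05)
        mat = pd.DataFrame([[0, 0, 0, 0]], index=["g"], columns=list("ABCD"))
        rec = cn.marginal_asr(mat, four_taxon_tree, model)
        for node in rec.node_labels:
            assert rec.posterior("g", node) < 0.5

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_enumeration_marginals(self, seed):
        rng = np.random.default_rng(1000 + seed)
        tree = random_tree(seed + 40, n_tips=int(rng.integers(3, 7)))
        model = cn.TwoStateModel(float(rng.uniform(0.05, 1.0)),
                                 float(rng.uniform(0.05, 1.0)))
        observed = {
            t: (int(rng.integers(0, 2)) if rng.uniform() > 0.2 else None)
            for t in tree.tip_labels()
        }
        row = {t: (np.nan if v is None else v) for t, v in observed.items()}
        mat = pd.DataFrame([row], index=["g"])
        rec = cn.marginal_asr(mat, tree, model)
        _, marg = enumeration_oracle(tree, observed, model)
        for node, expected in marg.items():
            assert rec.posterior("g", node) == pytest.approx(expected, abs=1e-10)


class TestFit:
    def test_rates_recovered_within_tolerance(self):
        tree = simulate.simulate_tree(simulate.TreeParams(n_tips=50), seed=0)
        q01, q10 = 0.004, 0.002
        params = simulate.DuplicationParams(
            n_genes=2000, base_gain=q01, burst_gain=q01, loss=q10,
            root_state="stationary",
        )
        mat, _, _ = simulate.simulate_duplications(tree, params, seed=77)
        model = cn.fit_two_state_model(mat, tree, frequency_mode="optimized")
        assert abs(model.q01 - q01) / q01 < 0.25
        assert abs(model.q10 - q10) / q10 < 0.25

    def test_empirical_mode_respects_observed_frequencies(self, four_taxon_tree):
        mat = pd.DataFrame(
            [[0, 0, 0, 1], [0, 0, 0, 0]], index=["g1", "g2"], columns=list("ABCD")
        )
        model = cn.fit_two_state_model(mat, four_taxon_tree, frequency_mode="empirical")
        assert model.pi[1] == pytest.approx(1 / 8, rel=1e-3)


class TestCallDuplications:
    def _recon(self, tree, post_map, gene="g"):
        labels = [n.label for n in tree.preorder()]
        post1 = np.array([[post_map.get(lab, 0.0) for lab in labels]])
        model = cn.TwoStateModel(0.1, 0.1)
        return cn.MarginalReconstruction([gene], labels, post1, model)

    def test_all_zero_reconstruction_no_events(self, four_taxon_tree):
        rec = self._recon(four_taxon_tree, {})
        events = cn.call_duplications(rec, four_taxon_tree)
        assert events.events == {}

    def test_confident_transition_called(self, four_taxon_tree):
        # parent N1 (clade AB) stays 0.05, child B jumps to 0.95
        rec = self._recon(four_taxon_tree, {"B": 0.95})
        events = cn.call_duplications(rec, four_taxon_tree)
        assert events.events == {"g": ["B"]}

    def test_uncertain_parent_blocks_call(self, four_taxon_tree):
        parent = four_taxon_tree.find("B").parent.label
        rec = self._recon(four_taxon_tree, {parent: 0.25, "B": 0.95})
        events = cn.call_duplications(rec, four_taxon_tree)
        assert events.events == {}
        assert events.diagnostics["unreliable_transitions"] == 1

    def test_one_event_per_path(self, four_taxon_tree):
        parent = four_taxon_tree.find("B").parent.label
        rec = self._recon(four_taxon_tree, {parent: 0.95, "B": 0.95, "A": 0.95})
        events = cn.call_duplications(rec, four_taxon_tree)
        # event on the internal branch; descendant branches are blocked
        assert events.events == {"g": [parent]}

    def test_raising_bpp_never_adds_events(self):
        tree = simulate.simulate_tree(simulate.TreeParams(n_tips=30), seed=5)
        params = simulate.DuplicationParams(n_genes=300)
        mat, _, _ = simulate.simulate_duplications(tree, params, seed=6)
        model = cn.fit_two_state_model(mat, tree)
        rec = cn.marginal_asr(mat, tree, model)
        previous = None
        for bpp in (0.5, 0.7, 0.8, 0.9, 0.99):
            n = sum(len(v) for v in cn.call_duplications(rec, tree, bpp).events.values())
            if previous is not None:
                assert n <= previous
            previous = n

    def test_event_precision_in_burst_scenario(self):
        tree = simulate.simulate_tree(simulate.TreeParams(n_tips=50), seed=11)
        params = simulate.DuplicationParams(n_genes=1000)
        mat, gains, bursts = simulate.simulate_duplications(tree, params, seed=12)
        model = cn.fit_two_state_model(mat, tree)
        rec = cn.marginal_asr(mat, tree, model)
        events = cn.call_duplications(rec, tree, bpp_min=0.80)
        tp = fp = 0
        for gene, branches in events.events.items():
            for b in branches:
                if b in gains[gene]:
                    tp += 1
                else:
                    fp += 1
        assert tp + fp > 0
        assert tp / (tp + fp) >= 0.9


class TestSummary:
    def test_counts_and_rates(self):
        ev = cn.DuplicationEventSet(
            events={f"g{i}": ["N5"] for i in range(100)}, n_genes=10_000, bpp_min=0.8
        )
        summary = cn.lineage_duplication_summary(ev)
        assert summary.iloc[0]["count"] == 100
        assert summary.iloc[0]["rate"] == pytest.approx(0.01)

    def test_branch_counts_conserve_total(self):
        ev = cn.DuplicationEventSet(
            events={"g1": ["a"], "g2": ["a", "b"], "g3": ["c"]},
            n_genes=3, bpp_min=0.8,
        )
        summary = cn.lineage_duplication_summary(ev)
        assert summary["count"].sum() == 4
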