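"""Synthetic corpus generators: trees, trait evolution, transfers, hit tables."""

import io
import math

import numpy as np
import pytest
from scipy import stats as sps

from domarch import profiles as prof
from domarch import synth
from domarch.asr import ErModel, fit_er_rate, marginal_posteriors, ASR_STATES
from domarch.treedist import cophenetic
from domarch.trees import node_depths, tree_to_string, validate_tree


class TestYuleTree:
    def test_two_leaves_is_a_cherry(self):
        tree = synth.simulate_yule_tree(2, 1.0, seed=0)
        assert len(tree.leaf_nodes()) == 2
        assert tree.seed_node.num_child_nodes() == 2

    def test_seed_determinism(self):
        a = tree_to_string(synth.simulate_yule_tree(32, 1.0, seed=5))
        b = tree_to_string(synth.simulate_yule_tree(32, 1.0, seed=5))
        assert a == b
        c = tree_to_string(synth.simulate_yule_tree(32, 1.0, seed=6))
        assert a != c

    def test_ultrametric_with_n_leaves(self):
        tree = synth.simulate_yule_tree(40, 2.0, seed=1)
        validate_tree(tree)
        depths = node_depths(tree)
        leaf_depths = [depths[lf] for lf in tree.leaf_node_iter()]
        assert len(leaf_depths) == 40
        assert np.allclose(leaf_depths, leaf_depths[0], atol=1e-12)

    def test_expected_height_pure_birth(self):
        """Mean height over replicates matches sum_{k=2..n} 1/(lambda k)
        within 3 standard errors (epoch durations are Exp(lambda k))."""
        n, lam, reps = 64, 1.0, 500
        heights = []
        for i in range(reps):
            tree = synth.simulate_yule_tree(n, lam, seed=10_000 + i)
            heights.append(max(node_depths(tree).values()))
        expected = sum(1.0 / (lam * k) for k in range(2, n + 1))
        var = sum(1.0 / (lam * k) ** 2 for k in range(2, n + 1))
        se = math.sqrt(var / reps)
        assert abs(np.mean(heights) - expected) < 3 * se


class TestErSimulation:
    def test_zero_rate_inherits_root_state(self):
        tree = synth.simulate_yule_tree(16, 1.0, seed=2)
        truth = synth.simulate_er_states(tree, ErModel(mu=0.0), "DC", seed=3)
        assert set(truth.leaf_states.values()) == {"DC"}
        assert truth.events == []

    def test_saturated_branch_reaches_uniform_stationary(self):
        """A branch with mu*t = 50 forgets the root state: leaf states are
        chi-square-consistent with the uniform distribution over 5 states."""
        counts = dict.fromkeys(ASR_STATES, 0)
        from domarch.trees import tree_from_string

        tree = tree_from_string("(A:50.0,B:0.0);")
        for i in range(5000):
            truth = synth.simulate_er_states(tree, ErModel(mu=1.0), "C", seed=i)
            counts[truth.leaf_states["A"]] += 1
        res = sps.chisquare(list(counts.values()))
        assert res.pvalue > 0.001

    def test_branch_end_state_matches_closed_form_kernel(self):
        """Monte-Carlo transition fractions on one branch agree with the
        analytic P(t) row within 3 binomial standard errors."""
        from domarch.asr import transition_matrix
        from domarch.trees import tree_from_string

        t, mu, reps = 0.8, 0.4, 10_000
        model = ErModel(mu=mu)
        tree = tree_from_string(f"(A:{t},B:0.0);")
        counts = dict.fromkeys(ASR_STATES, 0)
        for i in range(reps):
            truth = synth.simulate_er_states(tree, model, "C", seed=50_000 + i)
            counts[truth.leaf_states["A"]] += 1
        row = transition_matrix(model, t)[ASR_STATES.index("C")]
        for j, state in enumerate(ASR_STATES):
            p = row[j]
            se = math.sqrt(p * (1 - p) / reps)
            assert abs(counts[state] / reps - p) < 3 * se

    def test_node_states_consistent_with_event_history(self):
        tree = synth.simulate_yule_tree(32, 1.0, seed=4)
        truth = synth.simulate_er_states(tree, ErModel(mu=0.5), "C", seed=5)
        # a node whose branch saw no event inherits its parent's state
        event_nodes = {label for label, _, _ in truth.events}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            label = node.taxon.label if node.is_leaf() else node.label
            if label not in event_nodes:
                assert truth.node_states[node] == truth.node_states[node.parent_node]


class TestHgtInjection:
    def test_zero_rate_leaves_topology_unchanged(self):
        tree = synth.simulate_yule_tree(16, 1.0, seed=6)
        truth = synth.simulate_er_states(tree, ErModel(mu=0.1), "C", seed=7)
        truth, dtree = synth.inject_hgt(truth, hgt_rate=0.0, seed=8)
        assert truth.hgt_events == []
        assert tree_to_string(dtree) == tree_to_string(tree)

    def test_transfer_makes_recipient_sister_to_donor(self):
        tree = synth.simulate_yule_tree(16, 1.0, seed=9)
        truth = synth.simulate_er_states(tree, ErModel(mu=0.1), "C", seed=10)
        truth, dtree = synth.inject_hgt(truth, seed=11, n_events=1)
        assert len(truth.hgt_events) == 1
        ev = truth.hgt_events[0]
        validate_tree(dtree)
        assert len(dtree.leaf_nodes()) == 16
        sdm = cophenetic(tree)
        ddm = cophenetic(dtree)
        rec, don = ev["recipient_tips"][0], ev["donor_tips"][0]
        # the regrafted pair coalesces at the event time in the domain tree
        assert ddm.get(rec, don) < sdm.get(rec, don)
        depths = node_depths(tree)
        height = max(depths.values())
        assert ddm.get(rec, don) == pytest.approx(2 * (height - ev["time"]), rel=1e-9)

    def test_requested_event_count_is_applied(self):
        tree = synth.simulate_yule_tree(64, 1.0, seed=12)
        truth = synth.simulate_er_states(tree, ErModel(mu=0.1), "DCL", seed=13)
        truth, dtree = synth.inject_hgt(truth, seed=14, n_events=3)
        assert len(truth.hgt_events) == 3
        validate_tree(dtree)
        assert len(dtree.leaf_nodes()) == 64


class TestHitTables:
    def _corpus(self, noise=0.0, straddle=0.0, seed=20):
        config = synth.SimConfig(
            n_leaves=24, profile_noise=noise, straddle_fraction=straddle,
            species_oversampling={1: 0.7, 3: 0.3}, seed=seed,
        )
        tree = synth.simulate_yule_tree(config.n_leaves, 1.0, seed=seed)
        truth = synth.simulate_er_states(
            tree, ErModel(mu=0.3), "C", seed=seed + 1
        )
        strains = synth.expand_species_to_strains(
            truth.leaf_states, config, seed=seed + 2
        )
        taxon_map = {sp: "T" for sp in truth.leaf_states}
        texts = synth.generate_hit_tables(strains, taxon_map, config, seed=seed + 3)
        return strains, texts

    def _recover(self, texts):
        dom, blast, meta = texts
        hits = prof.filter_domain_hits(prof.parse_domtblout(io.StringIO(dom)))
        profiles = prof.build_profiles(hits)
        nuc = [h for h in prof.parse_blast_tab(io.StringIO(blast))
               if prof.rescue_filter(h)]
        return prof.strain_state_table(
            profiles, nuc, prof.read_metadata(io.StringIO(meta))
        )

    def test_zero_noise_roundtrip_recovers_every_state(self):
        strains, texts = self._corpus()
        recovered = self._recover(texts)
        want = {s.strain_id: (s.state, s.genomic_fragment) for s in strains}
        got = {s.strain_id: (s.state, s.genomic_fragment) for s in recovered}
        assert got == want

    def test_threshold_straddling_hits_are_all_removed(self):
        strains, texts = self._corpus(straddle=1.0)
        dom = texts[0]
        hits = prof.parse_domtblout(io.StringIO(dom))
        kept = prof.filter_domain_hits(hits)
        assert len(kept) < len(hits)  # straddle decoys were emitted...
        dropped = [h for h in hits if h not in kept]
        assert all(h.evalue > 1e-5 or h.model_coverage < 0.70 for h in dropped)
        # ...and their removal restores the exact true states
        recovered = self._recover(texts)
        want = {s.strain_id: s.state for s in strains}
        assert {s.strain_id: s.state for s in recovered} == want

    def test_determinism_under_seed(self):
        _, a = self._corpus(seed=31)
        _, b = self._corpus(seed=31)
        assert a == b


def test_end_to_end_root_state_recovery():
    """Simulate -> reconstruct: on 128-leaf height-1 trees at mu*height 0.1
    (a regime where the root signal is not yet mixed away), the MAP root
    state matches the simulated root in >= 80% of 50 runs."""
    recovered = 0
    for i in range(50):
        tree = synth.scale_to_height(
            synth.simulate_yule_tree(128, 1.0, seed=700 + i), 1.0
        )
        truth = synth.simulate_er_states(tree, ErModel(mu=0.1), "C", seed=800 + i)
        if len(set(truth.leaf_states.values())) < 2:
            recovered += 1  # monomorphic at the root state: trivially recovered
            continue
        fit = fit_er_rate(tree, truth.leaf_states)
        post = marginal_posteriors(tree, truth.leaf_states, ErModel(mu=fit.mu_hat))
        root_map = ASR_STATES[int(np.argmax(post[tree.seed_node]))]
        if root_map == truth.node_states[tree.seed_node]:
            recovered += 1
    assert recovered >= 0.8 * 50
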