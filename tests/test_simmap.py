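"""Stochastic-mapping sampler and ensemble summaries."""

import numpy as np
import pytest

import labile as lb
from labile.mk import _Propagator, _partials, _tip_state_indices
from labile.simmap import (CharacterHistory, Event, MappingEnsemble,
                           sample_history, summarize_ensemble)

PA = ("present", "absent")


def _er(q):
    return np.array([[-q, q], [q, -q]])


class TestSampleHistory:
    def test_zero_rates_give_zero_events(self, four_taxon_ultrametric):
        tips = {lb_: "present" for lb_ in four_taxon_ultrametric.tip_labels}
        h = sample_history(four_taxon_ultrametric, tips, np.zeros((2, 2)),
                           seed=0, states=PA)
        assert h.n_events == 0
        h.validate(four_taxon_ultrametric)

    @pytest.mark.parametrize("q,seed", [(0.1, 1), (0.8, 2), (3.0, 3)])
    def test_structural_invariants_hold(self, yule20, q, seed):
        rng = np.random.default_rng(seed)
        tips = {lb_: PA[i % 2] for i, lb_ in enumerate(yule20.tip_labels)}
        for _ in range(20):
            h = sample_history(yule20, tips, _er(q), rng=rng, states=PA)
            h.validate(yule20)

    def test_root_state_matches_pruning_posterior(self, three_taxon):
        # conditional root-state frequencies vs the exact posterior, 20k draws
        Q = np.array([[-0.3, 0.3], [0.2, -0.2]])
        tips = {"A": "x", "B": "y", "C": "x"}
        tid = _tip_state_indices(three_taxon, tips, ("x", "y"))
        P = _Propagator(Q)(three_taxon.edge_length)
        L, _ = _partials(three_taxon, tid, P)
        post = 0.5 * L[three_taxon.root]
        post /= post.sum()
        rng = np.random.default_rng(42)
        n = 20000
        counts = np.zeros(2)
        for _ in range(n):
            h = sample_history(three_taxon, tips, Q, rng=rng, states=("x", "y"))
            counts[h.node_states[three_taxon.root]] += 1
        freq = counts / n
        se = np.sqrt(post * (1 - post) / n)
        assert np.all(np.abs(freq - post) <= 3 * se)

    def test_rate_scaling_increases_event_counts(self, three_taxon):
        # stochastic monotonicity in the overall rate, one-sided test
        from scipy.stats import mannwhitneyu
        tips = {"A": "present", "B": "absent", "C": "present"}
        rng = np.random.default_rng(3)
        n = 10000
        lo = [sample_history(three_taxon, tips, _er(0.3), rng=rng,
                             states=PA).n_events for _ in range(n)]
        hi = [sample_history(three_taxon, tips, _er(0.9), rng=rng,
                             states=PA).n_events for _ in range(n)]
        assert np.mean(hi) > np.mean(lo)
        p = mannwhitneyu(hi, lo, alternative="greater").pvalue
        assert p < 0.01


class TestRunStochasticMapping:
    @pytest.fixture
    def records(self, yule20):
        rng = np.random.default_rng(8)
        recs, _, _ = lb.simulate_paired_bones(yule20, _er(0.01), _er(0.04),
                                              polymorphic_p=0.2, rng=rng)
        return recs

    def test_single_iteration_composes_sample_history(self, yule20, records):
        Q = lb.RateMatrix(_er(0.02), PA, "SYM")
        ens = lb.run_stochastic_mapping(yule20, records, bone="baculum",
                                        strategy="present", n_iter=1, seed=77, Q=Q)
        children = np.random.SeedSequence(77).spawn(2)
        coded = lb.recode_states(records, "baculum", "present")
        direct = sample_history(yule20, coded, Q,
                                rng=np.random.default_rng(children[0]))
        got = [(e.node, e.age, e.from_state, e.to_state)
               for e in ens.histories[0].events]
        want = [(e.node, e.age, e.from_state, e.to_state) for e in direct.events]
        assert got == want

    def test_same_seed_bitwise_identical(self, yule20, records):
        def events(seed):
            ens = lb.run_stochastic_mapping(yule20, records, bone="baubellum",
                                            strategy="random", n_iter=5, seed=seed)
            return [(e.node, e.age, e.from_state, e.to_state)
                    for h in ens.histories for e in h.events]
        assert events(123) == events(123)
        assert events(123) != events(124)

    def test_higher_rate_bone_has_more_transitions(self):
        # 50-tip tree, 4:1 rate asymmetry; rates kept below tip-signal
        # saturation (rate x depth <= 0.8) so mapped counts track the truth
        import warnings
        wins = 0
        for rep in range(20):
            rng = np.random.default_rng(300 + rep)
            tree = lb.simulate_yule_tree(50, rng=rng, depth=100.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # occasional monomorphic bone
                recs, _, _ = lb.simulate_paired_bones(tree, _er(0.002), _er(0.008),
                                                      polymorphic_p=0.0, rng=rng)
                means = {}
                for i, bone in enumerate(("baculum", "baubellum")):
                    ens = lb.run_stochastic_mapping(tree, recs, bone=bone,
                                                    strategy="present", n_iter=25,
                                                    seed=rep * 2 + i)
                    means[bone] = summarize_ensemble(ens).mean_total
            wins += means["baubellum"] > means["baculum"]
        assert wins >= 19  # >= 95% of 20 replicates


class TestSummarize:
    def _no_event_history(self, tree):
        segs = [[] if i == tree.root else [(0, float(tree.edge_length[i]))]
                for i in range(tree.n_nodes)]
        return CharacterHistory(node_states=np.zeros(tree.n_nodes, dtype=np.int64),
                                segments=segs, events=[], states=PA)

    def test_identical_no_event_histories(self, four_taxon_ultrametric):
        tree = four_taxon_ultrametric
        coded = lb.CodedDataset("present", "baculum", PA,
                                {lb_: "present" for lb_ in tree.tip_labels})
        ens = MappingEnsemble(tree=tree,
                              histories=[self._no_event_history(tree)] * 10,
                              coded=coded,
                              rate_matrix=lb.RateMatrix(np.zeros((2, 2)), PA, "ER"),
                              root_prior=np.array([0.5, 0.5]), seed=0)
        s = summarize_ensemble(ens)
        assert s.mean_total == 0 and s.sd_total == 0
        assert not s.high_confidence
        assert np.allclose(s.occupancy[:, 0], 1.0)

    def test_threshold_boundary_is_inclusive(self, four_taxon_ultrametric):
        tree = four_taxon_ultrametric
        branch = tree.tip_index("A")
        histories = []
        for i in range(10):
            h = self._no_event_history(tree)
            if i < 5:  # exactly half the iterations carry one event on A
                t = float(tree.edge_length[branch])
                h = CharacterHistory(
                    node_states=h.node_states.copy(),
                    segments=[list(s) for s in h.segments],
                    events=[Event(node=branch, age=tree.node_ages[branch] + t / 2,
                                  from_state=0, to_state=1)],
                    states=PA)
                h.segments[branch] = [(0, t / 2), (1, t / 2)]
                h.node_states[branch] = 1
            histories.append(h)
        coded = lb.CodedDataset("present", "baculum", PA,
                                {lb_: "present" for lb_ in tree.tip_labels})
        ens = MappingEnsemble(tree=tree, histories=histories, coded=coded,
                              rate_matrix=lb.RateMatrix(np.zeros((2, 2)), PA, "ER"),
                              root_prior=np.array([0.5, 0.5]), seed=0)
        s = summarize_ensemble(ens, confidence_threshold=0.5)
        hits = {h["branch"]: h for h in s.high_confidence}
        assert branch in hits
        assert hits[branch]["frequency"] == pytest.approx(0.5)
        assert hits[branch]["destination"] == "absent"

    def test_planted_loss_recovered_as_high_confidence(self):
        # one forced loss on a long internal branch is found in >= 18/20 ensembles
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(900 + rep)
            tree = lb.simulate_yule_tree(30, rng=rng, depth=100.0)
            # plant: a clade of >= 3 tips all absent, everything else present
            best = max((i for i in range(tree.n_nodes) if not tree.is_tip(i)
                        and i != tree.root),
                       key=lambda i: tree.edge_length[i])
            clade = [j for j in tree.tip_indices
                     if _has_ancestor(tree, j, best)]
            tips = {lab: "present" for lab in tree.tip_labels}
            for j in clade:
                tips[tree.labels[j]] = "absent"
            coded = lb.CodedDataset("present", "baculum", PA, tips)
            fit = lb.fit_mk(tree, coded, model="ER")
            rng2 = np.random.default_rng(10_000 + rep)
            branch_hit = 0
            n_it = 50
            for _ in range(n_it):
                h = sample_history(tree, coded, fit.rate_matrix, rng=rng2)
                if any(e.node == best for e in h.events):
                    branch_hit += 1
            hits += branch_hit / n_it >= 0.5
        assert hits >= 18

    def test_event_ages_within_tree_depth(self, yule20):
        tips = {lb_: PA[i % 2] for i, lb_ in enumerate(yule20.tip_labels)}
        rng = np.random.default_rng(0)
        for _ in range(10):
            h = sample_history(yule20, tips, _er(0.05), rng=rng, states=PA)
            for e in h.events:
                assert 0 <= e.age <= yule20.depth
                assert e.age < yule20.node_ages[yule20.parent[e.node]]


def _has_ancestor(tree, node, anc):
    while node != -1:
        if node == anc:
            return True
        node = tree.parent[node]
    return False
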