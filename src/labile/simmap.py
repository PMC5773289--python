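"""Stochastic character mapping: sampling full discrete-trait histories.

Given tip states and a fixed rate matrix (empirical-Bayes style, fixed at its
ML estimate), each mapping iteration draws

1. internal-node states from their joint conditional distribution given the
   tips (pruning partials followed by a root-to-tip pass), then
2. a continuous-time path along every branch conditional on its endpoint
   states, by forward rejection sampling with a retry cap and a
   uniformization fallback that guarantees termination on stiff branches.

Branches are identified by the index of their child node; event ages are in
My before present (age = tree depth - distance from root), increasing into
the past.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .mk import MkFit, RateMatrix, _Propagator, _partials, _resolve_prior, \
    _tip_state_indices, fit_mk
from .phylogeny import Phylogeny
from .traits import CodedDataset, TraitRecord, recode_states

__all__ = ["Event", "CharacterHistory", "MappingEnsemble", "EnsembleSummary",
           "sample_history", "run_stochastic_mapping", "summarize_ensemble"]

log = logging.getLogger(__name__)

_REJECTION_CAP = 1000


@dataclass(frozen=True)
class Event:
    """One state transition: on the branch above ``node``, at ``age`` My ago."""
    node: int
    age: float
    from_state: int
    to_state: int


@dataclass
class CharacterHistory:
    """One sampled trait history across the whole tree.

    ``segments[i]`` lists (state index, duration My) along the branch above
    node ``i``, parent-to-child order; the root has no branch and an empty
    list.  ``node_states[i]`` is the state at node ``i``.
    """
    node_states: np.ndarray
    segments: list[list[tuple[int, float]]]
    events: list[Event]
    states: tuple[str, ...]

    @property
    def n_events(self) -> int:
        return len(self.events)

    def events_by_type(self) -> dict[tuple[int, int], int]:
        out: dict[tuple[int, int], int] = {}
        for e in self.events:
            key = (e.from_state, e.to_state)
            out[key] = out.get(key, 0) + 1
        return out

    def time_in_state(self, tree: Phylogeny) -> np.ndarray:
        """Per-branch time fractions spent in each state, shape (n_nodes, k)."""
        k = len(self.states)
        out = np.zeros((tree.n_nodes, k))
        for i in range(tree.n_nodes):
            if i == tree.root:
                out[i, self.node_states[i]] = 1.0
                continue
            for st, dur in self.segments[i]:
                out[i, st] += dur
            tot = out[i].sum()
            if tot > 0:
                out[i] /= tot
            else:  # zero-length branch
                out[i, self.node_states[i]] = 1.0
        return out

    def validate(self, tree: Phylogeny, atol: float = 1e-9) -> None:
        """Check the structural invariants; raises AssertionError on failure."""
        ages = tree.node_ages
        n_from_segments = 0
        for i in range(tree.n_nodes):
            if i == tree.root:
                assert not self.segments[i]
                continue
            segs = self.segments[i]
            assert segs, f"empty segment list on branch {i}"
            total = sum(d for _, d in segs)
            assert abs(total - tree.edge_length[i]) <= atol * max(1.0, tree.edge_length[i]), \
                f"segment durations do not sum to branch length on {i}"
            assert segs[0][0] == self.node_states[tree.parent[i]]
            assert segs[-1][0] == self.node_states[i]
            for (a, _), (b, _) in zip(segs, segs[1:]):
                assert a != b, "adjacent segments with equal states"
            n_from_segments += len(segs) - 1
        assert n_from_segments == len(self.events)
        for e in self.events:
            lo, hi = ages[e.node], ages[tree.parent[e.node]]
            assert lo - atol <= e.age <= hi + atol, \
                f"event age {e.age} outside branch interval [{lo}, {hi}]"


@dataclass
class MappingEnsemble:
    """N stochastic-mapping iterations plus everything needed to re-run them."""
    tree: Phylogeny
    histories: list[CharacterHistory]
    coded: CodedDataset
    rate_matrix: RateMatrix
    root_prior: np.ndarray
    seed: int | None
    model: str = "SYM"
    per_iteration_Q: list[RateMatrix] | None = None

    @property
    def n_iter(self) -> int:
        return len(self.histories)

    @property
    def states(self) -> tuple[str, ...]:
        return self.coded.states


# ---------------------------------------------------------------------------
# endpoint-conditioned path sampling
# ---------------------------------------------------------------------------

def _forward_path(Q: np.ndarray, t: float, a: int, rng: np.random.Generator,
                  first_event_conditioned: bool) -> list[tuple[int, float]]:
    """Unconditional forward CTMC path from state ``a`` over duration ``t``.

    With ``first_event_conditioned`` the waiting time to the first event is
    drawn from an exponential truncated to (0, t) — the standard trick when
    the endpoints differ and at least one change must occur.
    """
    segs: list[tuple[int, float]] = []
    state, remaining = a, t
    first = True
    while True:
        rate = -Q[state, state]
        if rate <= 0:
            segs.append((state, remaining))
            return segs
        if first and first_event_conditioned:
            u = rng.random()
            wait = -np.log1p(-u * (1.0 - np.exp(-rate * remaining))) / rate
        else:
            wait = rng.exponential(1.0 / rate)
        first = False
        if wait >= remaining:
            segs.append((state, remaining))
            return segs
        segs.append((state, wait))
        remaining -= wait
        p = Q[state].copy()
        p[state] = 0.0
        state = int(rng.choice(len(p), p=p / p.sum()))


def _merge_segments(segs: list[tuple[int, float]]) -> list[tuple[int, float]]:
    out: list[tuple[int, float]] = []
    for st, d in segs:
        if out and out[-1][0] == st:
            out[-1] = (st, out[-1][1] + d)
        else:
            out.append((st, d))
    return out


def _uniformization_path(Q: np.ndarray, t: float, a: int, b: int,
                         rng: np.random.Generator) -> list[tuple[int, float]]:
    """Exact endpoint-conditioned path via the uniformized jump chain."""
    k = Q.shape[0]
    lam = float(np.max(-np.diag(Q)))
    if lam <= 0:
        if a != b:
            raise RuntimeError("zero-rate matrix cannot connect distinct endpoints")
        return [(a, t)]
    R = np.eye(k) + Q / lam
    # P(N = n | a -> b in t): Poisson(lam t) weighted by jump-chain kernel
    mu = lam * t
    powers = [np.eye(k)]
    weights = []
    logpois = -mu
    total = 0.0
    n = 0
    target = None
    u = rng.random()
    # P_ab(t) as normalizer, accumulated on the fly
    pab = 0.0
    terms = []
    while True:
        terms.append(np.exp(logpois) * powers[-1][a, b])
        pab += terms[-1]
        if n > 10 * mu + 100 and terms[-1] < 1e-16 * max(pab, 1e-300):
            break
        n += 1
        powers.append(powers[-1] @ R)
        logpois += np.log(mu) - np.log(n)
    if pab <= 0:
        raise RuntimeError("endpoint pair has zero probability under Q")
    probs = np.array(terms) / pab
    N = int(rng.choice(len(probs), p=probs))
    # jump chain conditioned on endpoints
    states = [a]
    for j in range(1, N + 1):
        prev = states[-1]
        w = R[prev, :] * powers[N - j][:, b]
        states.append(int(rng.choice(k, p=w / w.sum())))
    times = np.sort(rng.random(N)) * t
    segs: list[tuple[int, float]] = []
    last = 0.0
    for st, tm in zip(states[:-1], times):
        segs.append((st, tm - last))
        last = tm
    segs.append((states[-1], t - last))
    segs = _merge_segments([s for s in segs if s[1] > 0 or len(segs) == 1])
    if not segs:
        segs = [(a, t)]
    return segs


def _sample_branch(Q: np.ndarray, t: float, a: int, b: int,
                   rng: np.random.Generator,
                   cap: int = _REJECTION_CAP) -> list[tuple[int, float]]:
    """Endpoint-conditioned path a -> b over t: rejection then uniformization."""
    if t <= 0:
        if a != b:
            raise RuntimeError("zero-length branch with distinct endpoint states")
        return [(a, t)]
    for _ in range(cap):
        segs = _forward_path(Q, t, a, rng, first_event_conditioned=(a != b))
        if segs[-1][0] == b:
            return _merge_segments(segs)
    return _uniformization_path(Q, t, a, b, rng)


# ---------------------------------------------------------------------------
# whole-tree sampling
# ---------------------------------------------------------------------------

def sample_history(tree: Phylogeny, coded: CodedDataset | Mapping[str, str],
                   Q: RateMatrix | np.ndarray, root_prior="uniform",
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   states: Sequence[str] | None = None) -> CharacterHistory:
    """Draw one character history consistent with the coded tip states."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if states is None:
        if not isinstance(coded, CodedDataset):
            raise ValueError("states must be given when coded is a plain mapping")
        states = coded.states
    Qm = Q.Q if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    k = Qm.shape[0]
    pi = _resolve_prior(root_prior, k)
    tip_idx = _tip_state_indices(tree, coded, states)
    P = _Propagator(Qm)(tree.edge_length)
    L, _ = _partials(tree, tip_idx, P)
    if L is None:
        raise RuntimeError("tip states have zero likelihood under Q")

    node_states = np.full(tree.n_nodes, -1, dtype=np.int64)
    w = pi * L[tree.root]
    node_states[tree.root] = rng.choice(k, p=w / w.sum())
    for i in range(1, tree.n_nodes):  # preorder
        s = node_states[tree.parent[i]]
        w = P[i][s] * L[i]
        node_states[i] = rng.choice(k, p=w / w.sum())

    depth = tree.depth
    depths = tree.node_depths
    segments: list[list[tuple[int, float]]] = [[] for _ in range(tree.n_nodes)]
    events: list[Event] = []
    for i in range(1, tree.n_nodes):
        a, b = int(node_states[tree.parent[i]]), int(node_states[i])
        segs = _sample_branch(Qm, float(tree.edge_length[i]), a, b, rng)
        segments[i] = segs
        elapsed = 0.0
        parent_depth = depths[tree.parent[i]]
        for (st, dur), (nxt, _) in zip(segs, segs[1:]):
            elapsed += dur
            events.append(Event(node=i, age=depth - (parent_depth + elapsed),
                                from_state=st, to_state=nxt))
    return CharacterHistory(node_states=node_states, segments=segments,
                            events=events, states=tuple(states))


def run_stochastic_mapping(tree: Phylogeny, records: Sequence[TraitRecord],
                           bone: str, strategy: str, n_iter: int = 1000,
                           model: str = "SYM", root_prior="uniform",
                           seed: int | None = None,
                           redraw_random_per_iteration: bool = True,
                           Q: RateMatrix | None = None) -> MappingEnsemble:
    """Recode, fit Q, and sample ``n_iter`` histories for one bone.

    Reproducible from ``seed``: a master ``SeedSequence`` spawns one child
    stream per iteration (children ``0..n_iter-1``; child ``n_iter`` drives
    the random-strategy recoding), so ensembles are stable under
    parallelization of iterations.

    Under the ``random`` strategy the present/absent assignment of each
    polymorphic species is redrawn every iteration by default (integrating
    over assignment uncertainty); Q is then re-fit once per distinct
    assignment, with caching.  Set ``redraw_random_per_iteration=False`` to
    freeze a single assignment.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    tips = set(tree.tip_labels)
    have = {r.species for r in records}
    if not tips <= have:
        raise ValueError(f"tree tips without trait records: {sorted(tips - have)[:10]}")
    records = [r for r in records if r.species in tips]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_iter + 1)
    recode_rng = np.random.default_rng(children[n_iter])

    fit_cache: dict[tuple, MkFit] = {}

    def fit_for(coded: CodedDataset) -> MkFit:
        key = tuple(sorted(coded.codes.items()))
        if key not in fit_cache:
            fit_cache[key] = fit_mk(tree, coded, model=model, root_prior=root_prior)
        return fit_cache[key]

    redraw = strategy == "random" and redraw_random_per_iteration
    base_coded = recode_states(records, bone, strategy,
                               seed=seed if strategy == "random" else None,
                               rng=recode_rng if strategy == "random" else None)
    base_fit = MkFit(Q, np.nan, _resolve_prior(root_prior, len(base_coded.states))) \
        if Q is not None else fit_for(base_coded)

    histories: list[CharacterHistory] = []
    per_iter_Q: list[RateMatrix] = []
    for it in range(n_iter):
        rng = np.random.default_rng(children[it])
        if redraw:
            coded = recode_states(records, bone, strategy, rng=recode_rng)
            fit = MkFit(Q, np.nan, base_fit.root_prior) if Q is not None else fit_for(coded)
        else:
            coded, fit = base_coded, base_fit
        histories.append(sample_history(tree, coded, fit.rate_matrix,
                                        root_prior=fit.root_prior, rng=rng))
        per_iter_Q.append(fit.rate_matrix)
    log.info("stochastic mapping: bone=%s strategy=%s n_iter=%d model=%s "
             "unique Q fits=%d", bone, strategy, n_iter, model, len(fit_cache))
    return MappingEnsemble(tree=tree, histories=histories, coded=base_coded,
                           rate_matrix=base_fit.rate_matrix,
                           root_prior=base_fit.root_prior, seed=seed, model=model,
                           per_iteration_Q=per_iter_Q if redraw else None)


# ---------------------------------------------------------------------------
# ensemble summaries
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSummary:
    """Transition counts, ages, branch frequencies and occupancies of an ensemble."""
    states: tuple[str, ...]
    totals: np.ndarray                      # (N,) per-iteration event counts
    type_counts: dict[tuple[str, str], np.ndarray]  # per directed type, (N,)
    type_mean_sd: dict[tuple[str, str], tuple[float, float]]
    branch_frequency: np.ndarray            # (n_nodes,) P(>=1 event on branch)
    modal_destination: list[str | None]     # per branch
    occupancy: np.ndarray                   # (n_nodes, k) mean time fractions
    high_confidence: list[dict]             # branches with freq >= threshold
    ages: np.ndarray                        # flat event ages (My)
    age_iteration: np.ndarray               # iteration index per age
    age_types: list[tuple[str, str]]
    confidence_threshold: float = 0.5

    @property
    def mean_total(self) -> float:
        return float(self.totals.mean())

    @property
    def sd_total(self) -> float:
        return float(self.totals.std(ddof=1)) if len(self.totals) > 1 else 0.0

    @property
    def mean_age(self) -> float:
        return float(self.ages.mean()) if self.ages.size else np.nan

    def to_json(self) -> str:
        payload = {
            "states": list(self.states),
            "n_iter": int(len(self.totals)),
            "mean_total_transitions": self.mean_total,
            "sd_total_transitions": self.sd_total,
            "mean_transition_age_my": None if np.isnan(self.mean_age) else self.mean_age,
            "per_type": {f"{a}->{b}": {"mean": m, "sd": s}
                         for (a, b), (m, s) in self.type_mean_sd.items()},
            "high_confidence_branches": self.high_confidence,
            "confidence_threshold": self.confidence_threshold,
        }
        return json.dumps(payload, indent=2)


def summarize_ensemble(ens: MappingEnsemble,
                       confidence_threshold: float = 0.5) -> EnsembleSummary:
    """Totals, per-type counts, high-confidence branches and occupancies.

    A branch is a high-confidence transition if at least
    ``confidence_threshold`` of the iterations place one or more events on it
    (inclusive threshold); it is labelled with the most frequent destination
    state among its events.
    """
    if not ens.histories:
        raise ValueError("empty ensemble")
    tree, states = ens.tree, ens.states
    k = len(states)
    N = ens.n_iter
    n_nodes = tree.n_nodes

    totals = np.zeros(N, dtype=np.int64)
    type_counts = {(a, b): np.zeros(N, dtype=np.int64)
                   for a in states for b in states if a != b}
    hit = np.zeros((N, n_nodes), dtype=bool)
    dest_counts = np.zeros((n_nodes, k), dtype=np.int64)
    occupancy = np.zeros((n_nodes, k))
    ages, age_iter, age_types = [], [], []

    for it, h in enumerate(ens.histories):
        totals[it] = h.n_events
        for e in h.events:
            type_counts[(states[e.from_state], states[e.to_state])][it] += 1
            hit[it, e.node] = True
            dest_counts[e.node, e.to_state] += 1
            ages.append(e.age)
            age_iter.append(it)
            age_types.append((states[e.from_state], states[e.to_state]))
        occupancy += h.time_in_state(tree)
    occupancy /= N

    branch_freq = hit.mean(axis=0)
    modal = [states[int(np.argmax(dest_counts[i]))] if dest_counts[i].sum() else None
             for i in range(n_nodes)]
    high = [{"branch": int(i),
             "child_label": tree.labels[i],
             "frequency": float(branch_freq[i]),
             "destination": modal[i]}
            for i in range(n_nodes)
            if i != tree.root and branch_freq[i] >= confidence_threshold]
    type_mean_sd = {key: (float(v.mean()), float(v.std(ddof=1)) if N > 1 else 0.0)
                    for key, v in type_counts.items()}
    return EnsembleSummary(states=states, totals=totals, type_counts=type_counts,
                           type_mean_sd=type_mean_sd, branch_frequency=branch_freq,
                           modal_destination=modal, occupancy=occupancy,
                           high_confidence=high, ages=np.asarray(ages, dtype=float),
                           age_iteration=np.asarray(age_iter, dtype=np.int64),
                           age_types=age_types,
                           confidence_threshold=confidence_threshold)


def events_to_tsv(ens: MappingEnsemble) -> str:
    """All ensemble events as TSV (branch ids = child-node index, see header)."""
    lines = ["# branch_id = index of the branch's child node (preorder; root=0)",
             "iteration\tbranch_id\tchild_label\tage_my\tfrom\tto"]
    states = ens.states
    for it, h in enumerate(ens.histories):
        for e in h.events:
            lines.append(f"{it}\t{e.node}\t{ens.tree.labels[e.node] or ''}\t"
                         f"{e.age:.6f}\t{states[e.from_state]}\t{states[e.to_state]}")
    return "\n".join(lines) + "\n"


def occupancy_to_tsv(summary: EnsembleSummary, tree: Phylogeny) -> str:
    header = "branch_id\tchild_label\t" + "\t".join(
        f"frac_{s}" for s in summary.states)
    lines = ["# branch_id = index of the branch's child node (preorder; root=0)",
             header]
    for i in range(tree.n_nodes):
        fr = "\t".join(f"{x:.6f}" for x in summary.occupancy[i])
        lines.append(f"{i}\t{tree.labels[i] or ''}\t{fr}")
    return "\n".join(lines) + "\n"
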