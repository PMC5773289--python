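"""Synthetic data with the statistical structure the analyses assume.

Generates (i) ultrametric pure-birth (Yule) trees rescaled to a target root
age so ages read in My; (ii) exact Gillespie forward simulations of discrete
traits under an Mk rate matrix, returning full true histories; (iii) paired
"bone" datasets in which the female-trait rate matrix is more labile than the
male's and present-state female tips may be recorded as polymorphic; and
(iv) normally distributed length measurements with specified group CVs.

Defaults emulate the comparative study conditions the package targets:
a 163-species ultrametric tree of depth 100 My, a 2-state gain/loss process
with the female bone four times as labile as the male's, and a 12%
polymorphic recording probability for present female bones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .cv import GroupSummary
from .mk import RateMatrix
from .phylogeny import Phylogeny
from .simmap import CharacterHistory, Event, _forward_path, _merge_segments
from .traits import TraitRecord

__all__ = ["SimulationConfig", "simulate_yule_tree", "simulate_mk_forward",
           "simulate_paired_bones", "simulate_measurement_groups"]

PA = ("present", "absent")


def _sym2(rate: float) -> np.ndarray:
    return np.array([[-rate, rate], [rate, -rate]], dtype=float)


def _asym2(loss: float, gain: float) -> np.ndarray:
    # state order (present, absent); loss = present -> absent
    return np.array([[-loss, loss], [gain, -gain]], dtype=float)


@dataclass
class SimulationConfig:
    """Study-condition defaults for the full synthetic pipeline."""
    n_tips: int = 163
    birth_rate: float = 1.0            # per My (shape only; depth is rescaled)
    tree_depth: float = 100.0          # My
    # male bone: loss-dominated (losses are rarely regained); female bone:
    # freely labile, with a 4:1 female:male loss-rate ratio
    q_bac: np.ndarray = field(default_factory=lambda: _asym2(0.004, 0.001))
    q_bau: np.ndarray = field(default_factory=lambda: _sym2(0.016))
    polymorphic_p: float = 0.12
    couple_bones: bool = True
    measurement_spec: tuple = ((5, 8.0, 0.30), (5, 80.0, 0.08))  # (n, mean, cv)
    seed: int | None = None

    def __post_init__(self):
        if self.n_tips < 3:
            raise ValueError("n_tips must be >= 3")
        if not (0 <= self.polymorphic_p <= 1):
            raise ValueError("polymorphic_p must be a probability")
        for Q in (self.q_bac, self.q_bau):
            Q = np.asarray(Q, dtype=float)
            if np.any(Q[~np.eye(len(Q), dtype=bool)] < 0):
                raise ValueError("rates must be nonnegative")


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int | None = None,
                       rng: np.random.Generator | None = None,
                       depth: float | None = None) -> Phylogeny:
    """Ultrametric pure-birth tree with exactly ``n_tips`` tips.

    Lineages split at total rate (lineages alive) x birth_rate; after the
    n-th lineage appears, all pending branches are extended by one final
    exponential waiting time so terminal branches are positive.  With
    ``depth`` given, branch lengths are rescaled so the root-to-tip distance
    equals it exactly.  Reproducible from ``seed``.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    # nodes are created after their parents, so indices are preorder-valid
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]   # time at which the branch above each node starts
    end = [0.0, None, None]   # time at which it ends (split time, or present)
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = active.pop(int(rng.integers(len(active))))
        end[i] = t
        for _ in range(2):
            parent.append(i)
            birth.append(t)
            end.append(None)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / (birth_rate * n_tips))
    for i in active:
        end[i] = t_end

    lengths = [0.0] + [end[i] - birth[i] for i in range(1, len(parent))]
    labels: list[str | None] = [None] * len(parent)
    internal = set(parent)
    tip_counter = 0
    for i in range(len(parent)):
        if i not in internal:  # leaf: never became a parent
            tip_counter += 1
            labels[i] = f"t{tip_counter}"
    tree = Phylogeny(parent, lengths, labels)
    if depth is not None:
        tree = tree.rescale(depth / tree.depth)
    return tree


def simulate_mk_forward(tree: Phylogeny, Q: RateMatrix | np.ndarray,
                        root_state: int | str = 0,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        states: Sequence[str] | None = None
                        ) -> tuple[CharacterHistory, dict[str, str]]:
    """Exact Gillespie simulation of an Mk trait down the tree.

    Returns the full true history (valid input to the ensemble summaries)
    and the per-species tip states.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(Q, RateMatrix):
        Qm, st = Q.Q, Q.states
    else:
        Qm = np.asarray(Q, dtype=float)
        st = tuple(states) if states is not None else tuple(
            PA if len(Qm) == 2 else [f"state{i}" for i in range(len(Qm))])
    if isinstance(root_state, str):
        root_state = st.index(root_state)

    n = tree.n_nodes
    node_states = np.full(n, -1, dtype=np.int64)
    node_states[tree.root] = root_state
    segments: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    events: list[Event] = []
    depth = tree.depth
    depths = tree.node_depths
    for i in range(1, n):  # preorder
        a = int(node_states[tree.parent[i]])
        segs = _merge_segments(
            _forward_path(Qm, float(tree.edge_length[i]), a, rng,
                          first_event_conditioned=False))
        segments[i] = segs
        node_states[i] = segs[-1][0]
        elapsed = 0.0
        parent_depth = depths[tree.parent[i]]
        for (s, dur), (nxt, _) in zip(segs, segs[1:]):
            elapsed += dur
            events.append(Event(node=i, age=depth - (parent_depth + elapsed),
                                from_state=s, to_state=nxt))
    tips = {tree.labels[i]: st[node_states[i]] for i in tree.tip_indices}
    history = CharacterHistory(node_states=node_states, segments=segments,
                               events=events, states=st)
    return history, tips


def simulate_paired_bones(tree: Phylogeny,
                          Q_bac: RateMatrix | np.ndarray,
                          Q_bau: RateMatrix | np.ndarray,
                          polymorphic_p: float = 0.12,
                          couple: bool = True,
                          root_state: str = "present",
                          seed: int | None = None,
                          rng: np.random.Generator | None = None
                          ) -> tuple[list[TraitRecord], CharacterHistory, CharacterHistory]:
    """Paired male/female bone datasets with an asymmetric lability.

    Both bones evolve independently as 2-state present/absent Mk processes
    (the female trait typically with the faster rate matrix).  With
    ``couple=True`` the recorded female state is forced to absent wherever
    the male bone is absent at the tip — species that lack the male bone
    never show the female one — mirroring the empirical one-way coupling.
    A present female tip is recorded as polymorphic with probability
    ``polymorphic_p`` (observation-level noise; the returned true histories
    are unmodified).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    hist_bac, tips_bac = simulate_mk_forward(tree, Q_bac, root_state=root_state,
                                             rng=rng, states=PA)
    hist_bau, tips_bau = simulate_mk_forward(tree, Q_bau, root_state=root_state,
                                             rng=rng, states=PA)
    records = []
    for sp in tree.tip_labels:
        bac = tips_bac[sp]
        bau = tips_bau[sp]
        if couple and bac == "absent":
            bau = "absent"
        if bau == "present" and polymorphic_p > 0 and rng.random() < polymorphic_p:
            bau = "polymorphic"
        records.append(TraitRecord(species=sp, baculum=bac, baubellum=bau))
    return records, hist_bac, hist_bau


def simulate_measurement_groups(spec: Sequence[tuple[int, float, float]],
                                seed: int | None = None,
                                rng: np.random.Generator | None = None
                                ) -> tuple[list[np.ndarray], list[GroupSummary]]:
    """Normal length measurements for groups specified as (n, mean, cv).

    Returns the raw samples and GroupSummary objects computed from them.
    Negative values are permitted (the CV tests assume plain normality), but
    a spec whose normal model would put 50% or more mass below zero is
    rejected as unrealistic.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    samples: list[np.ndarray] = []
    summaries: list[GroupSummary] = []
    for n, mean, cv in spec:
        if n < 2:
            raise ValueError("each group needs n >= 2")
        if mean <= 0:
            raise ValueError("group means must be positive")
        if cv < 0:
            raise ValueError("cv must be nonnegative")
        if cv > 0 and norm.cdf(-1.0 / cv) >= 0.5:
            raise ValueError(f"spec (n={n}, mean={mean}, cv={cv}) puts >= 50% "
                             "of the normal mass below zero")
        x = rng.normal(mean, cv * mean, size=n)
        samples.append(x)
        summaries.append(GroupSummary(n=int(n), mean=float(x.mean()),
                                      sd=float(x.std(ddof=1))))
    return samples, summaries
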