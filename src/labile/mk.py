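"""Mk (k-state continuous-time Markov) models of discrete trait evolution.

Provides the CTMC transition kernel, the Felsenstein pruning likelihood and
maximum-likelihood estimation of the transition rate matrix under the usual
constraint families:

ER
    equal rates: one rate shared by all transitions;
SYM
    symmetric rates: q_ij = q_ji;
ARD
    all rates different.

Rates are per million years.  For two states ER and SYM coincide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
from scipy.optimize import minimize, minimize_scalar

from .phylogeny import Phylogeny
from .traits import CodedDataset

__all__ = ["RateMatrix", "MkFit", "transition_probability_matrix",
           "prune_loglik", "fit_mk"]

log = logging.getLogger(__name__)

CONSTRAINTS = ("ER", "SYM", "ARD")
_RATE_FLOOR = 1e-9


@dataclass(frozen=True)
class RateMatrix:
    """A k-state transition rate matrix (per My) with a constraint tag."""
    Q: np.ndarray
    states: tuple[str, ...]
    constraint: str = "ARD"

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "Q", Q)
        k = len(self.states)
        if Q.shape != (k, k):
            raise ValueError(f"Q must be {k}x{k} for states {self.states}")
        off = Q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be nonnegative")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-10 * max(1.0, np.max(np.abs(Q))):
            raise ValueError("rows of Q must sum to zero")
        if self.constraint not in CONSTRAINTS:
            raise ValueError(f"constraint must be one of {CONSTRAINTS}")
        if self.constraint == "SYM" and not np.allclose(Q, Q.T, atol=1e-12):
            raise ValueError("SYM requires q_ij = q_ji")
        if self.constraint == "ER" and off.size and np.ptp(off) > 1e-12 * max(off.max(), 1e-300):
            raise ValueError("ER requires all off-diagonal rates equal")

    @property
    def k(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class MkFit:
    """Result of a maximum-likelihood Mk fit."""
    rate_matrix: RateMatrix
    loglik: float
    root_prior: np.ndarray
    monomorphic: bool = False


def _as_Q(Q: RateMatrix | np.ndarray) -> np.ndarray:
    return Q.Q if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)


def transition_probability_matrix(Q: RateMatrix | np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt): the state-to-state transition kernel over t My."""
    if t < 0:
        raise ValueError(f"elapsed time must be >= 0, got {t}")
    P = scipy.linalg.expm(_as_Q(Q) * t)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


class _Propagator:
    """Fast exp(Q t) across many branch lengths via eigendecomposition.

    Falls back to scipy's expm when the eigenvector basis is ill-conditioned
    (possible for strongly asymmetric Q).
    """

    def __init__(self, Q: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self._ok = False
        try:
            w, V = np.linalg.eig(self.Q)
            cond = np.linalg.cond(V)
            if np.isfinite(cond) and cond < 1e8:
                self.w, self.V, self.Vinv = w, V, np.linalg.inv(V)
                self._ok = True
        except np.linalg.LinAlgError:
            pass

    def __call__(self, lengths: np.ndarray) -> np.ndarray:
        lengths = np.asarray(lengths, dtype=float)
        if self._ok:
            ew = np.exp(np.multiply.outer(lengths, self.w))  # (E, k)
            P = np.einsum("ik,ek,kj->eij", self.V, ew, self.Vinv).real
        else:
            P = np.stack([scipy.linalg.expm(self.Q * t) for t in lengths])
        P = np.clip(P, 0.0, None)
        return P / P.sum(axis=2, keepdims=True)


def _tip_state_indices(tree: Phylogeny, coded: CodedDataset | Mapping[str, str],
                       states: Sequence[str]) -> np.ndarray:
    codes = coded.codes if isinstance(coded, CodedDataset) else coded
    missing = [lb for lb in tree.tip_labels if lb not in codes]
    if missing:
        raise ValueError(f"species without a coded state: {sorted(missing)}")
    idx = np.full(tree.n_nodes, -1, dtype=np.int64)
    lookup = {s: i for i, s in enumerate(states)}
    for i in tree.tip_indices:
        idx[i] = lookup[codes[tree.labels[i]]]
    return idx


def _resolve_prior(root_prior, k: int) -> np.ndarray:
    if isinstance(root_prior, str):
        if root_prior != "uniform":
            raise ValueError(f"unknown root prior {root_prior!r}")
        return np.full(k, 1.0 / k)
    pi = np.asarray(root_prior, dtype=float)
    if pi.shape != (k,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise ValueError("root prior must be a length-k probability vector")
    return pi


def _partials(tree: Phylogeny, tip_idx: np.ndarray, P: np.ndarray):
    """Per-node conditional likelihood arrays and the per-tree log scale.

    ``P[i]`` is the propagator along the edge above node ``i``.  Returns
    (partials (n,k), log_scale) where partials are rescaled per node to avoid
    underflow.
    """
    n = tree.n_nodes
    k = P.shape[1]
    L = np.empty((n, k))
    log_scale = 0.0
    for i in tree.postorder:
        if tree.is_tip(i):
            L[i] = 0.0
            L[i, tip_idx[i]] = 1.0
        else:
            v = np.ones(k)
            for c in tree.children[i]:
                v = v * (P[c] @ L[c])
            s = v.max()
            if s <= 0:
                return None, -np.inf
            L[i] = v / s
            log_scale += np.log(s)
    return L, log_scale


def prune_loglik(tree: Phylogeny, coded: CodedDataset | Mapping[str, str],
                 Q: RateMatrix | np.ndarray, root_prior="uniform",
                 states: Sequence[str] | None = None) -> float:
    """Felsenstein pruning log-likelihood of the tip states under Q."""
    if states is None:
        if not isinstance(coded, CodedDataset):
            raise ValueError("states must be given when coded is a plain mapping")
        states = coded.states
    Qm = _as_Q(Q)
    k = Qm.shape[0]
    if len(states) != k:
        raise ValueError("state space size does not match Q")
    tip_idx = _tip_state_indices(tree, coded, states)
    pi = _resolve_prior(root_prior, k)
    P = _Propagator(Qm)(tree.edge_length)
    L, log_scale = _partials(tree, tip_idx, P)
    if L is None:
        return -np.inf
    lik = float(pi @ L[tree.root])
    if lik <= 0:
        return -np.inf
    return np.log(lik) + log_scale


def _constraint_structure(k: int, constraint: str) -> list[list[tuple[int, int]]]:
    """Groups of (i, j) off-diagonal cells sharing one free rate."""
    cells = [(i, j) for i in range(k) for j in range(k) if i != j]
    if constraint == "ER":
        return [cells]
    if constraint == "SYM":
        return [[(i, j), (j, i)] for i in range(k) for j in range(i + 1, k)]
    if constraint == "ARD":
        return [[c] for c in cells]
    raise ValueError(f"constraint must be one of {CONSTRAINTS}")


def _build_Q(rates: np.ndarray, k: int, structure) -> np.ndarray:
    Q = np.zeros((k, k))
    for r, group in zip(rates, structure):
        for i, j in group:
            Q[i, j] = r
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def fit_mk(tree: Phylogeny, coded: CodedDataset, model: str = "SYM",
           root_prior="uniform") -> MkFit:
    """Maximum-likelihood Mk rate matrix under an ER/SYM/ARD constraint.

    The free rates are optimized on a log scale from several starting values
    spanning slow to fast regimes relative to tree depth.  Monomorphic tip
    data drive the rates to the lower bound (with a warning).
    """
    states = coded.states
    k = len(states)
    tip_idx = _tip_state_indices(tree, coded, states)
    pi = _resolve_prior(root_prior, k)
    structure = _constraint_structure(k, model)
    n_par = len(structure)
    depth = max(tree.depth, 1e-12)
    lo, hi = np.log(_RATE_FLOOR), np.log(1e4 / depth)

    observed = {int(tip_idx[i]) for i in tree.tip_indices}
    if len(observed) < 2:
        warnings.warn("monomorphic tip states: rates fixed at the lower bound")
        Q = _build_Q(np.full(n_par, _RATE_FLOOR), k, structure)
        rm = RateMatrix(Q, states, model)
        return MkFit(rm, prune_loglik(tree, coded, rm, pi), pi, monomorphic=True)

    def negloglik(log_rates: np.ndarray) -> float:
        Q = _build_Q(np.exp(np.atleast_1d(log_rates)), k, structure)
        P = _Propagator(Q)(tree.edge_length)
        L, log_scale = _partials(tree, tip_idx, P)
        if L is None:
            return 1e300
        lik = float(pi @ L[tree.root])
        if lik <= 0 or not np.isfinite(lik):
            return 1e300
        return -(np.log(lik) + log_scale)

    starts = np.log(np.array([0.05, 0.5, 5.0]) / depth)
    best_x, best_f = None, np.inf
    if n_par == 1:
        res = minimize_scalar(lambda x: negloglik(np.array([x])),
                              bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10})
        best_x, best_f = np.array([res.x]), res.fun
    else:
        for s in starts:
            res = minimize(negloglik, np.full(n_par, s), method="L-BFGS-B",
                           bounds=[(lo, hi)] * n_par,
                           options={"ftol": 1e-12, "gtol": 1e-9})
            if res.fun < best_f:
                best_x, best_f = res.x, res.fun
    Q = _build_Q(np.exp(best_x), k, structure)
    rm = RateMatrix(Q, states, model)
    log.info("fit_mk: model=%s logL=%.6f rates=%s", model, -best_f,
             np.exp(best_x).round(8).tolist())
    return MkFit(rm, -float(best_f), pi)
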