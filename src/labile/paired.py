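"""Phylogenetically controlled paired t-test.

Tests whether paired within-species differences (here: female CV minus male
CV) have nonzero mean while accounting for shared evolutionary history.  The
differences d are modelled as

    d ~ Normal(mu * 1, sigma^2 * C(lambda)),

where C is the Brownian-motion covariance of the tips (shared root-to-MRCA
path lengths) and lambda in [0, 1] rescales its off-diagonal entries
(Pagel's lambda signal parameter).  (mu, sigma^2, lambda) are estimated by
joint maximum likelihood; t = mu_hat / SE(mu_hat) is referred to a t
distribution with n - 3 degrees of freedom (three estimated parameters),
matching the convention of the standard R implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import t as t_dist

from .phylogeny import Phylogeny

__all__ = ["PairedTTestResult", "phylo_paired_ttest"]


@dataclass(frozen=True)
class PairedTTestResult:
    mean_diff: float
    se: float
    t: float
    df: int
    p: float
    lam: float
    sigma2: float
    loglik: float


def _profile_loglik(lam: float, C: np.ndarray, d: np.ndarray):
    """(logL, mu_hat, sigma2_hat, se_mu) with (mu, sigma2) profiled at lambda."""
    n = len(d)
    Cl = C * lam
    np.fill_diagonal(Cl, np.diag(C))
    try:
        cho = np.linalg.cholesky(Cl)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, np.nan, np.nan
    one = np.ones(n)
    sol = np.linalg.solve
    a = sol(cho, one)
    b = sol(cho, d)
    ctc = a @ a                  # 1' C^-1 1
    mu = (a @ b) / ctc
    r = b - mu * a
    rss = r @ r
    sigma2 = rss / n             # ML (not REML) scale, used in the likelihood
    if sigma2 <= 0:
        return -np.inf, mu, sigma2, np.nan
    logdet = 2 * np.log(np.diag(cho)).sum()
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    # SE on the unbiased (n-1) scale so that a star phylogeny recovers the
    # ordinary one-sample t statistic exactly
    se = np.sqrt(rss / (n - 1) / ctc)
    return ll, mu, sigma2, se


def phylo_paired_ttest(tree: Phylogeny,
                       pairs: Mapping[str, float] | tuple[Sequence[str], Sequence[float]],
                       h0: float = 0.0) -> PairedTTestResult:
    """Paired t-test of per-species differences under BM covariance.

    ``pairs`` maps species (tree tip labels) to their paired difference, or
    is a (labels, values) pair.  All species must be tips of ``tree``;
    a non-ultrametric tree triggers a warning (the BM model still applies but
    tip variances are then unequal by depth).
    """
    if isinstance(pairs, Mapping):
        labels = list(pairs)
        d = np.array([pairs[lb] for lb in labels], dtype=float)
    else:
        labels, values = pairs
        labels = list(labels)
        d = np.asarray(values, dtype=float)
    if len(labels) != len(d):
        raise ValueError("labels and values differ in length")
    if len(labels) < 4:
        raise ValueError("need at least 4 species")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    missing = sorted(set(labels) - set(tree.tip_labels))
    if missing:
        raise ValueError(f"species missing from the tree: {missing}")
    if not tree.is_ultrametric():
        warnings.warn("tree is not ultrametric; tip variances are unequal")

    sub = tree
    if set(labels) != set(tree.tip_labels):
        from .phylogeny import prune_to_taxa
        sub = prune_to_taxa(tree, labels)
    C = sub.shared_path_matrix(labels)

    res = minimize_scalar(lambda lam: -_profile_loglik(lam, C, d)[0],
                          bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": 1e-8})
    candidates = [res.x, 0.0, 1.0]
    lam = max(candidates, key=lambda l: _profile_loglik(l, C, d)[0])
    ll, mu, sigma2, se = _profile_loglik(lam, C, d)
    n = len(d)
    df = n - 3
    if np.ptp(d) == 0 and np.all(d == h0):
        tval = 0.0
    else:
        tval = (mu - h0) / se
    p = 2 * float(t_dist.sf(abs(tval), df))
    return PairedTTestResult(mean_diff=float(mu), se=float(se), t=float(tval),
                             df=df, p=p, lam=float(lam), sigma2=float(sigma2),
                             loglik=float(ll))
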