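"""Comparing transition counts and transition times between two bones.

Per-iteration total transition counts are compared with a Wilcoxon rank-sum
test.  Transition ages are compared with a likelihood-ratio test on a
random-intercept linear mixed model

    age = b0 + b1 * I(bone = baubellum) + u_iter + e,
    u_iter ~ N(0, su^2),  e ~ N(0, s^2),

fit by maximum likelihood (not REML, since the LRT is on a fixed effect);
the iteration intercept absorbs the dependence of ages sampled within one
mapping iteration.  The LRT statistic is referred to chi-square with 1 df.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, mannwhitneyu

from .simmap import MappingEnsemble, summarize_ensemble

__all__ = ["WilcoxonResult", "LRTResult", "wilcoxon_rank_sum",
           "lmm_lrt_bone_effect", "compare_bones", "BoneComparison"]

_EXACT_N = 20  # below this, and tie-free, the rank-sum null is enumerated


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float          # rank-sum W of the first sample
    p: float
    n_x: int
    n_y: int
    method: str               # "exact" or "asymptotic"


@dataclass(frozen=True)
class LRTResult:
    chi_square: float
    df: int
    p: float
    bone_effect: float        # fixed-effect mean age difference (My)
    var_iteration: float      # random-intercept variance
    var_residual: float
    deviance_full: float
    deviance_reduced: float


def wilcoxon_rank_sum(x, y) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test on two independent samples.

    Exact null enumeration when both samples are smaller than 20 and tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < pooled.size
    exact = min(x.size, y.size) < _EXACT_N and not ties
    res = mannwhitneyu(x, y, alternative="two-sided",
                       method="exact" if exact else "asymptotic",
                       use_continuity=True)
    w = float(res.statistic + x.size * (x.size + 1) / 2)  # U -> rank-sum W
    return WilcoxonResult(statistic=w, p=float(res.pvalue), n_x=x.size,
                          n_y=y.size, method="exact" if exact else "asymptotic")


# ---------------------------------------------------------------------------
# random-intercept LMM by profiled maximum likelihood
# ---------------------------------------------------------------------------

def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group sums needed for the Woodbury-form profiled likelihood."""
    uniq, inv = np.unique(groups, return_inverse=True)
    g = len(uniq)
    n_g = np.bincount(inv).astype(float)
    p = X.shape[1]
    Sx = np.zeros((g, p))
    Sy = np.zeros(g)
    for j in range(p):
        Sx[:, j] = np.bincount(inv, weights=X[:, j])
    Sy = np.bincount(inv, weights=y)
    return n_g, Sx, Sy


def _profile_deviance(gamma: float, XtX, Xty, yty, n_g, Sx, Sy, N):
    """-2 logL maximized over (beta, sigma^2) at fixed gamma = su^2/s^2."""
    a = gamma / (1.0 + gamma * n_g)           # per-group Woodbury weight
    A = XtX - (Sx * a[:, None]).T @ Sx
    b = Xty - Sx.T @ (a * Sy)
    c = yty - float(a @ (Sy ** 2))
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    rss = c - 2 * beta @ b + beta @ A @ beta
    if rss <= 0:
        return np.inf, None, None
    sigma2 = rss / N
    logdet_extra = float(np.log1p(gamma * n_g).sum())
    dev = N * math.log(2 * math.pi * sigma2) + logdet_extra + N
    return dev, beta, sigma2


def _fit_lmm_ml(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                tol: float = 1e-8):
    """ML fit of y = X beta + u_group + e; returns (deviance, beta, su2, s2)."""
    N = len(y)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    n_g, Sx, Sy = _group_stats(X, y, groups)

    def dev_at(log_gamma: float) -> float:
        return _profile_deviance(math.exp(log_gamma), XtX, Xty, yty,
                                 n_g, Sx, Sy, N)[0]

    res = minimize_scalar(dev_at, bounds=(-14.0, 14.0), method="bounded",
                          options={"xatol": 1e-10})
    candidates = [(res.fun, math.exp(res.x))]
    dev0, _, _ = _profile_deviance(0.0, XtX, Xty, yty, n_g, Sx, Sy, N)
    candidates.append((dev0, 0.0))
    dev, gamma = min(candidates, key=lambda t: t[0])
    if not np.isfinite(dev):
        raise ValueError("degenerate data: zero residual variance in the mixed model")
    dev, beta, sigma2 = _profile_deviance(gamma, XtX, Xty, yty, n_g, Sx, Sy, N)
    return dev, beta, gamma * sigma2, sigma2


def lmm_lrt_bone_effect(ages, bones, iterations) -> LRTResult:
    """LRT for a bone fixed effect on transition ages, chi-square df=1.

    Parameters are parallel arrays: transition age (My), bone label (the
    reference level is the lexicographically first; the effect is the mean
    age difference of the second level), and mapping-iteration index (the
    random-intercept grouping shared across bones).
    """
    ages = np.asarray(ages, dtype=float)
    bone_arr = np.asarray(bones)
    iters = np.asarray(iterations)
    levels = sorted(set(bone_arr.tolist()))
    if len(levels) != 2:
        raise ValueError(f"exactly two bone labels required, got {levels}")
    if len(set(iters.tolist())) < 2:
        raise ValueError("at least 2 iterations required")
    if np.ptp(ages) == 0:
        raise ValueError("degenerate data: all transition ages identical "
                         "(zero residual variance)")
    ind = (bone_arr == levels[1]).astype(float)
    X_full = np.column_stack([np.ones_like(ages), ind])
    X_red = np.ones((len(ages), 1))
    dev_full, beta, su2, s2 = _fit_lmm_ml(X_full, ages, iters)
    dev_red, _, _, _ = _fit_lmm_ml(X_red, ages, iters)
    stat = max(dev_red - dev_full, 0.0)
    return LRTResult(chi_square=float(stat), df=1, p=float(chi2.sf(stat, 1)),
                     bone_effect=float(beta[1]), var_iteration=float(su2),
                     var_residual=float(s2), deviance_full=float(dev_full),
                     deviance_reduced=float(dev_red))


# ---------------------------------------------------------------------------
# whole-ensemble comparison
# ---------------------------------------------------------------------------

@dataclass
class BoneComparison:
    """Counts, ages and tests comparing two mapping ensembles."""
    bone_x: str
    bone_y: str
    n_iter: int
    mean_count_x: float
    sd_count_x: float
    mean_count_y: float
    sd_count_y: float
    type_mean_sd_x: dict
    type_mean_sd_y: dict
    wilcoxon: WilcoxonResult
    mean_age_x: float
    mean_age_y: float
    lrt: LRTResult

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=float)


def compare_bones(ens_x: MappingEnsemble, ens_y: MappingEnsemble) -> BoneComparison:
    """Compare two bones' ensembles mapped on the same tree.

    Iterations are paired by index across the two ensembles so that the
    mixed model's random intercept is shared; the rank-sum test on totals
    treats the two count vectors as independent samples.
    """
    if ens_x.n_iter != ens_y.n_iter:
        raise ValueError("ensembles have different iteration counts")
    if ens_x.tree.to_newick() != ens_y.tree.to_newick():
        raise ValueError("ensembles were mapped on different trees")
    sx = summarize_ensemble(ens_x)
    sy = summarize_ensemble(ens_y)
    bx = ens_x.coded.bone
    by = ens_y.coded.bone
    w = wilcoxon_rank_sum(sx.totals, sy.totals)
    ages = np.concatenate([sx.ages, sy.ages])
    bones = np.array([bx] * sx.ages.size + [by] * sy.ages.size)
    iters = np.concatenate([sx.age_iteration, sy.age_iteration])
    lrt = lmm_lrt_bone_effect(ages, bones, iters)
    return BoneComparison(
        bone_x=bx, bone_y=by, n_iter=ens_x.n_iter,
        mean_count_x=sx.mean_total, sd_count_x=sx.sd_total,
        mean_count_y=sy.mean_total, sd_count_y=sy.sd_total,
        type_mean_sd_x={f"{a}->{b}": v for (a, b), v in sx.type_mean_sd.items()},
        type_mean_sd_y={f"{a}->{b}": v for (a, b), v in sy.type_mean_sd.items()},
        wilcoxon=w, mean_age_x=sx.mean_age, mean_age_y=sy.mean_age, lrt=lrt)
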