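"""Equality tests for coefficients of variation of bone lengths.

Works from per-group summary statistics (n, mean, SD) — the form in which
published bone-length data are available — or from raw measurement vectors.
The coefficient of variation is CV = SD/mean and its standard error is
CV/sqrt(2N).

Two tests of H0: equal CVs across groups under normal models are provided:

* the asymptotic chi-square test of Feltz & Miller (1996), based on a pooled
  CV with (n_i - 1) weights;
* a modified signed-likelihood-ratio test (Krishnamoorthy & Lee 2014): the
  likelihood-ratio statistic for a common CV, calibrated by dividing by its
  null expectation estimated from seeded Monte-Carlo simulation at the
  constrained ML fit (a Bartlett-type small-sample correction), referred to
  chi-square with k-1 df.

``min_sample_size`` escalates a balanced per-sex sample size until the
asymptotic test reaches significance with the observed CVs held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

__all__ = ["GroupSummary", "CVResult", "CVTestResult", "cv_with_se",
           "summarize_sample", "feltz_miller_asymptotic", "mslr_test",
           "min_sample_size", "build_cv_table"]

MSLR_DEFAULT_NR = 10_000
_MIN_N_CAP = 10 ** 6


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean and SD of one sex's bone lengths (mm)."""
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if int(self.n) != self.n or self.n < 2:
            raise ValueError(f"n must be an integer >= 2, got {self.n}")
        if not (self.mean > 0):
            raise ValueError(f"mean must be positive, got {self.mean}")
        if self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")

    @property
    def cv(self) -> float:
        return self.sd / self.mean


@dataclass(frozen=True)
class CVResult:
    cv: float
    se: float


@dataclass(frozen=True)
class CVTestResult:
    statistic: float
    df: int
    p: float
    method: str  # "asymptotic" or "mslr"


def summarize_sample(x) -> GroupSummary:
    """GroupSummary (n, mean, ddof=1 SD) of a raw measurement vector."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 measurements")
    return GroupSummary(n=int(x.size), mean=float(x.mean()),
                        sd=float(x.std(ddof=1)))


def cv_with_se(g: GroupSummary) -> CVResult:
    """CV = sd/mean and its standard error CV/sqrt(2n)."""
    cv = g.sd / g.mean
    return CVResult(cv=cv, se=cv / math.sqrt(2 * g.n))


def _as_n_cv(groups) -> tuple[np.ndarray, np.ndarray]:
    ns, cvs = [], []
    for g in groups:
        if isinstance(g, GroupSummary):
            ns.append(g.n)
            cvs.append(g.cv)
        else:
            n, cv = g
            if n < 2:
                raise ValueError("each group needs n >= 2")
            ns.append(n)
            cvs.append(float(cv))
    return np.asarray(ns, dtype=float), np.asarray(cvs, dtype=float)


def feltz_miller_asymptotic(groups: Sequence) -> CVTestResult:
    """Feltz-Miller asymptotic chi-square test of CV equality.

    ``groups``: GroupSummary objects or (n, cv) pairs, k >= 2.  The pooled CV
    weights each group's CV by n_i - 1; the statistic is

        sum (n_i - 1)(cv_i - cv_p)^2 / [cv_p^2 (0.5 + cv_p^2)]

    on chi-square with k - 1 df.
    """
    ns, cvs = _as_n_cv(groups)
    if len(ns) < 2:
        raise ValueError("need at least 2 groups")
    if np.all(cvs == 0):
        raise ValueError("all CVs are zero: the statistic is undefined")
    w = ns - 1.0
    cv_p = float(w @ cvs / w.sum())
    stat = float(w @ (cvs - cv_p) ** 2 / (cv_p ** 2 * (0.5 + cv_p ** 2)))
    df = len(ns) - 1
    return CVTestResult(statistic=stat, df=df, p=float(chi2.sf(stat, df)),
                        method="asymptotic")


# ---------------------------------------------------------------------------
# modified signed-likelihood ratio test
# ---------------------------------------------------------------------------

def _mu_hat(tau, n, xbar, s2):
    # constrained ML mean: root of tau^2 mu^2 + xbar mu - ((n-1)s2/n + xbar^2)
    c = (n - 1) * s2 / n + xbar ** 2
    return (-xbar + np.sqrt(xbar ** 2 + 4 * tau ** 2 * c)) / (2 * tau ** 2)


def _loglik_unrestricted(ns, s2s):
    # at mu_i = xbar_i, sigma2_i = (n_i-1) s_i^2 / n_i (2*pi terms dropped)
    return sum(-0.5 * n * np.log((n - 1) * s2 / n) - 0.5 * n
               for n, s2 in zip(ns, s2s))


def _loglik_constrained(log_tau, ns, xbars, s2s):
    tau = np.exp(log_tau)
    tot = 0.0
    for n, xbar, s2 in zip(ns, xbars, s2s):
        mu = _mu_hat(tau, n, xbar, s2)
        sig2 = (tau * mu) ** 2
        ss = (n - 1) * s2 + n * (xbar - mu) ** 2
        tot = tot - 0.5 * n * np.log(sig2) - ss / (2 * sig2)
    return tot


def _lrt_observed(ns, xbars, s2s) -> tuple[float, float]:
    res = minimize_scalar(lambda lt: -_loglik_constrained(lt, ns, xbars, s2s),
                          bounds=(-14.0, 4.0), method="bounded",
                          options={"xatol": 1e-13})
    if not np.isfinite(res.fun):
        raise RuntimeError("constrained CV fit failed to converge "
                           f"(groups: n={ns}, xbar={xbars}, s2={s2s})")
    lrt = max(2 * (_loglik_unrestricted(ns, s2s) - (-res.fun)), 0.0)
    return lrt, float(np.exp(res.x))


def _lrt_vectorized(ns, xbars, s2s) -> np.ndarray:
    """LRT over many simulated summary datasets; golden-section over log tau.

    ``xbars``/``s2s`` have shape (k, R) for R replicates.
    """
    R = xbars.shape[1]
    lo = np.full(R, -14.0)
    hi = np.full(R, 4.0)
    gr = (math.sqrt(5) - 1) / 2

    def f(lt):
        tau = np.exp(lt)
        tot = 0.0
        for i, n in enumerate(ns):
            mu = _mu_hat(tau, n, xbars[i], s2s[i])
            sig2 = (tau * mu) ** 2
            ss = (n - 1) * s2s[i] + n * (xbars[i] - mu) ** 2
            tot = tot - 0.5 * n * np.log(sig2) - ss / (2 * sig2)
        return tot

    c = hi - gr * (hi - lo)
    d = lo + gr * (hi - lo)
    fc, fd = f(c), f(d)
    for _ in range(70):  # interval shrinks to ~1e-6 of 18 units
        m = fc > fd
        hi = np.where(m, d, hi)
        lo = np.where(m, lo, c)
        c = hi - gr * (hi - lo)
        d = lo + gr * (hi - lo)
        fc, fd = f(c), f(d)
    l0 = np.maximum(fc, fd)
    l1 = sum(-0.5 * n * np.log((n - 1) * s2s[i] / n) - 0.5 * n
             for i, n in enumerate(ns))
    return np.maximum(2 * (l1 - l0), 0.0)


def mslr_test(groups: Sequence[GroupSummary], nr: int = MSLR_DEFAULT_NR,
              seed: int = 0) -> CVTestResult:
    """Modified signed-likelihood ratio test for CV equality.

    The likelihood-ratio statistic for a common CV (normal model, constrained
    optimum found numerically) is divided by its null mean estimated from
    ``nr`` seeded Monte-Carlo replicates of the per-group summary statistics
    at the constrained ML fit, and referred to chi-square with k-1 df.
    Deterministic for a fixed seed; Monte-Carlo error of the statistic is
    about 1.4% at the default nr.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups], dtype=float)
    xbars = np.array([g.mean for g in groups], dtype=float)
    s2s = np.array([g.sd ** 2 for g in groups], dtype=float)
    if np.any(s2s <= 0):
        raise ValueError("every group needs a positive SD for the MSLR test")
    lrt, tau0 = _lrt_observed(ns, xbars, s2s)

    rng = np.random.default_rng(seed)
    mus = np.array([_mu_hat(tau0, n, xb, s2)
                    for n, xb, s2 in zip(ns, xbars, s2s)])
    sim_xbar = np.empty((len(ns), nr))
    sim_s2 = np.empty((len(ns), nr))
    for i, (n, mu) in enumerate(zip(ns, mus)):
        sig = tau0 * abs(mu)
        sim_xbar[i] = mu + sig / math.sqrt(n) * rng.standard_normal(nr)
        sim_s2[i] = sig ** 2 * rng.chisquare(n - 1, nr) / (n - 1)
    null_mean = float(_lrt_vectorized(ns, sim_xbar, sim_s2).mean())
    if not np.isfinite(null_mean) or null_mean <= 0:
        raise RuntimeError("MSLR null calibration failed "
                           f"(null mean = {null_mean})")
    stat = lrt / null_mean
    df = len(ns) - 1
    return CVTestResult(statistic=float(stat), df=df,
                        p=float(chi2.sf(stat, df)), method="mslr")


# ---------------------------------------------------------------------------
# sample-size escalation
# ---------------------------------------------------------------------------

def min_sample_size(g_f: GroupSummary, g_m: GroupSummary,
                    alpha: float = 0.05, cap: int = _MIN_N_CAP) -> int | None:
    """Smallest balanced per-sex n at which the asymptotic test is significant.

    Both sexes' CVs are held fixed at their unrounded sd/mean while the
    common sample size n is increased from 2; returns the first n with
    p < alpha (strict), or None if no n <= cap achieves it (equal CVs).
    """
    cv_f, cv_m = g_f.cv, g_m.cv
    if cv_f == cv_m:
        return None
    crit = chi2.ppf(1 - alpha, 1)
    # equal weights make the pooled CV independent of n: statistic = (n-1)*c
    c = feltz_miller_asymptotic([(2, cv_f), (2, cv_m)]).statistic
    if c <= 0:
        return None
    start = max(2, math.floor(crit / c) - 1)
    n = start
    while n <= cap:
        p = feltz_miller_asymptotic([(n, cv_f), (n, cv_m)]).p
        if p < alpha:
            # confirm minimality against the scan origin
            if n == 2 or feltz_miller_asymptotic([(n - 1, cv_f), (n - 1, cv_m)]).p >= alpha:
                return n
            n -= 1
            continue
        n += 1
    return None


# ---------------------------------------------------------------------------
# batch table
# ---------------------------------------------------------------------------

def build_cv_table(rows: Sequence[tuple[str, GroupSummary, GroupSummary]],
                   alpha: float = 0.05, mslr_nr: int = MSLR_DEFAULT_NR,
                   mslr_seed: int = 0) -> pd.DataFrame:
    """Per-species CV comparison table (one row per species, both sexes).

    Emits n/mean/sd/CV/SE per sex, both test statistics with p-values and
    significance flags, and the minimum balanced sample size — reported only
    where neither test is significant at ``alpha`` (the convention of
    published summary tables, which dash out the column otherwise).
    """
    out = []
    for species, g_f, g_m in rows:
        r_f = cv_with_se(g_f)
        r_m = cv_with_se(g_m)
        asym = feltz_miller_asymptotic([g_f, g_m])
        mslr = mslr_test([g_f, g_m], nr=mslr_nr, seed=mslr_seed)
        sig_a = asym.p <= alpha
        sig_m = mslr.p <= alpha
        min_n = None if (sig_a or sig_m) else min_sample_size(g_f, g_m, alpha=alpha)
        out.append({
            "species": species,
            "n_f": g_f.n, "mean_f": g_f.mean, "sd_f": g_f.sd,
            "cv_f": r_f.cv, "se_f": r_f.se,
            "n_m": g_m.n, "mean_m": g_m.mean, "sd_m": g_m.sd,
            "cv_m": r_m.cv, "se_m": r_m.se,
            "asymptotic_stat": asym.statistic, "asymptotic_p": asym.p,
            "asymptotic_significant": sig_a,
            "mslr_stat": mslr.statistic, "mslr_p": mslr.p,
            "mslr_significant": sig_m,
            "min_sample_size": min_n,
        })
    cols = ["species", "n_f", "mean_f", "sd_f", "cv_f", "se_f",
            "n_m", "mean_m", "sd_m", "cv_m", "se_m",
            "asymptotic_stat", "asymptotic_p", "asymptotic_significant",
            "mslr_stat", "mslr_p", "mslr_significant", "min_sample_size"]
    return pd.DataFrame(out, columns=cols)
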