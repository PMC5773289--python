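"""Rank-sum test, random-intercept LRT, and whole-ensemble comparison."""

import numpy as np
import pytest

import labile as lb
from labile.compare import _fit_lmm_ml, lmm_lrt_bone_effect, wilcoxon_rank_sum


class TestWilcoxon:
    def test_exact_enumeration_small_samples(self):
        # all 6 arrangements of ranks: two-sided p = 1/3 for maximal separation
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p == pytest.approx(1 / 3, abs=1e-12)
        assert res.statistic == pytest.approx(3.0)  # ranks 1 + 2

    def test_identical_multisets_not_significant(self):
        x = list(range(30))
        res = wilcoxon_rank_sum(x, list(x))
        assert res.method == "asymptotic"  # ties force the normal approximation
        assert res.p > 0.99

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(10, 1000)
        y = rng.poisson(10, 1000) + 5
        assert wilcoxon_rank_sum(x, y).p < 1e-10

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(8, 40).astype(float)
        y = rng.poisson(11, 35).astype(float)
        p1 = wilcoxon_rank_sum(x, y).p
        p2 = wilcoxon_rank_sum(np.exp(x / 5), np.exp(y / 5)).p
        assert p1 == pytest.approx(p2, abs=1e-12)


def _simulate_lmm(rng, n_iter=60, per=4, beta1=0.0, su=2.0, s=5.0):
    u = rng.normal(0, su, n_iter)
    ages, bones, iters = [], [], []
    for it in range(n_iter):
        for bone, shift in (("bac", 0.0), ("bau", beta1)):
            ages.extend(40 + shift + u[it] + rng.normal(0, s, per))
            bones.extend([bone] * per)
            iters.extend([it] * per)
    return np.array(ages), np.array(bones), np.array(iters)


def _direct_deviance(y, X, groups, beta, su2, s2):
    """-2 x multivariate-normal log-likelihood, computed group by group."""
    dev = 0.0
    for g in np.unique(groups):
        m = groups == g
        r = y[m] - X[m] @ beta
        V = s2 * np.eye(m.sum()) + su2 * np.ones((m.sum(), m.sum()))
        sign, logdet = np.linalg.slogdet(V)
        dev += m.sum() * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r)
    return dev


class TestLmmLrt:
    def test_deviance_matches_direct_mvn(self):
        rng = np.random.default_rng(2)
        y, bones, iters = _simulate_lmm(rng, beta1=3.0)
        X = np.column_stack([np.ones_like(y), (bones == "bau").astype(float)])
        dev, beta, su2, s2 = _fit_lmm_ml(X, y, iters)
        assert dev == pytest.approx(_direct_deviance(y, X, iters, beta, su2, s2),
                                    abs=1e-8)

    def test_deviance_beats_grid(self):
        # ML optimum is at least as good as a 20x20 grid around it
        rng = np.random.default_rng(3)
        y, bones, iters = _simulate_lmm(rng, beta1=2.0)
        X = np.column_stack([np.ones_like(y), (bones == "bau").astype(float)])
        dev, beta, su2, s2 = _fit_lmm_ml(X, y, iters)
        for su2_g in np.linspace(max(su2 * 0.2, 1e-3), su2 * 3 + 1, 20):
            for s2_g in np.linspace(s2 * 0.5, s2 * 2, 20):
                assert dev <= _direct_deviance(y, X, iters, beta, su2_g, s2_g) + 1e-6

    def test_collapses_to_ols_lr_without_grouping(self):
        # one observation per group: the mixed model degenerates to OLS, and
        # the LRT equals the standard ML likelihood-ratio statistic
        rng = np.random.default_rng(4)
        n = 120
        x = rng.integers(0, 2, n).astype(float)
        y = 10 + 2 * x + rng.normal(0, 5, n)
        res = lmm_lrt_bone_effect(y, np.where(x > 0, "bau", "bac"), np.arange(n))
        X = np.column_stack([np.ones(n), x])
        rss1 = np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        assert res.chi_square == pytest.approx(n * np.log(rss0 / rss1), abs=1e-6)

    def test_location_invariance(self):
        rng = np.random.default_rng(5)
        y, bones, iters = _simulate_lmm(rng, beta1=1.5)
        a = lmm_lrt_bone_effect(y, bones, iters)
        b = lmm_lrt_bone_effect(y + 1000.0, bones, iters)
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-5)
        assert a.bone_effect == pytest.approx(b.bone_effect, abs=1e-6)

    def test_shuffled_labels_rarely_significant(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(600 + rep)
            y, bones, iters = _simulate_lmm(rng, n_iter=40, beta1=4.0)
            # shuffle bone labels within iteration: destroys the bone effect
            for it in np.unique(iters):
                m = iters == it
                bones[m] = rng.permutation(bones[m])
            res = lmm_lrt_bone_effect(y, bones, iters)
            hits += res.chi_square < 3.84
        assert hits >= 18  # >= 90%

    def test_degenerate_ages_rejected(self):
        with pytest.raises(ValueError, match="zero residual variance|identical"):
            lmm_lrt_bone_effect([5.0] * 8, ["bac", "bau"] * 4, [0, 0, 1, 1, 2, 2, 3, 3])

    def test_statsmodels_never_beats_us(self):
        # independent implementation: statsmodels MixedLM (ML) deviance
        MixedLM = pytest.importorskip(
            "statsmodels.regression.mixed_linear_model").MixedLM
        rng = np.random.default_rng(6)
        y, bones, iters = _simulate_lmm(rng, beta1=2.5)
        X = np.column_stack([np.ones_like(y), (bones == "bau").astype(float)])
        dev, *_ = _fit_lmm_ml(X, y, iters)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = MixedLM(y, X, groups=iters).fit(reml=False)
        if np.isfinite(sm_fit.llf):
            assert dev <= -2 * sm_fit.llf + 1e-4


@pytest.fixture(scope="module")
def small_setup():
    rng = np.random.default_rng(12)
    tree = lb.simulate_yule_tree(25, rng=rng, depth=100.0)
    recs, _, _ = lb.simulate_paired_bones(
        tree, np.array([[-.004, .004], [.001, -.001]]),
        np.array([[-.016, .016], [.016, -.016]]),
        polymorphic_p=0.15, rng=rng)
    return tree, recs


class TestCompareBones:

    def test_self_comparison_is_null(self, small_setup):
        tree, recs = small_setup
        a = lb.run_stochastic_mapping(tree, recs, bone="baubellum",
                                      strategy="present", n_iter=40, seed=5)
        b = lb.run_stochastic_mapping(tree, recs, bone="baubellum",
                                      strategy="present", n_iter=40, seed=5)
        b.coded = lb.CodedDataset("present", "baculum", b.coded.states, b.coded.codes)
        comp = lb.compare_bones(a, b)
        assert comp.wilcoxon.p > 0.9
        assert comp.lrt.chi_square < 3.84

    def test_rate_asymmetry_detected(self, small_setup):
        tree, recs = small_setup
        ens = {}
        for i, bone in enumerate(("baculum", "baubellum")):
            ens[bone] = lb.run_stochastic_mapping(tree, recs, bone=bone,
                                                  strategy="present",
                                                  n_iter=100, seed=40 + i)
        comp = lb.compare_bones(ens["baculum"], ens["baubellum"])
        assert comp.mean_count_y > comp.mean_count_x
        assert comp.wilcoxon.p < 0.01

    def test_mismatched_iteration_counts_rejected(self, small_setup):
        tree, recs = small_setup
        a = lb.run_stochastic_mapping(tree, recs, bone="baculum",
                                      strategy="present", n_iter=5, seed=1)
        b = lb.run_stochastic_mapping(tree, recs, bone="baubellum",
                                      strategy="present", n_iter=6, seed=1)
        with pytest.raises(ValueError, match="iteration"):
            lb.compare_bones(a, b)
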