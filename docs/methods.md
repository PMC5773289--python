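# Methods

## Trees, ages and units

Phylogenies are rooted, with branch lengths in millions of years (My).  Node
age = tree depth − distance from the root, so tips of an ultrametric tree are
at age 0 and ages increase into the past; every transition age is reported on
this "My before present" scale.  Newick parsing and validation are delegated
to dendropy; the in-memory container is an array-backed preorder structure
tuned for repeated pruning passes.  Pruning to a taxon subset suppresses
unary nodes with branch lengths summed, preserving patristic distances
exactly.  Species in a trait table but not on the tree are dropped with a
warning; taxon aliases (e.g., substituting a close relative that is on the
tree) are applied at read time via a two-column CSV.

## Mk model and stochastic mapping

Discrete traits evolve by a k-state continuous-time Markov (Mk) process with
rate matrix Q (per My).  Constraints: ER (one rate), SYM (q_ij = q_ji,
default, equal to ER for two states), ARD.  The likelihood of the coded tip
states is computed by Felsenstein pruning with per-node rescaling; exp(Qt)
across all branches is computed from one eigendecomposition of Q (scipy expm
fallback when the eigenbasis is ill-conditioned, condition number >= 1e8).
ML rates are optimized on a log scale in [1e-9, 1e4/depth] (bounded scalar
search for one free rate, L-BFGS-B from three starts spanning 0.05–5 expected
changes per depth otherwise).  Monomorphic tip data yield rates at the lower
bound with a warning.

Mapping is empirical Bayes: Q is fixed at its MLE (re-fit once per distinct
assignment, cached, when the `random` polymorphic coding redraws assignments
each iteration), the root prior is uniform by default, node states are drawn
from their joint conditional distribution (pruning partials, then a
root-to-tip pass), and each branch path is drawn conditional on its endpoint
states: forward rejection sampling — with the first waiting time drawn from a
truncated exponential when the endpoints differ — capped at 1,000 attempts,
then exact uniformization (jump chain of R = I + Q/Λ conditioned on the
endpoints, uniform order-statistics event times, virtual jumps merged).  The
sampler is validated against a naive forward-rejection oracle (chi-square
GOF on event-count distributions, 20,000 draws) and against the exact
root-state posterior.

Seed management: a master `SeedSequence` spawns one child stream per
iteration (child n_iter drives random-strategy recoding), so ensembles are
bit-reproducible and safely parallelizable.

Ensemble summaries count every state change as an event (multiple events of
the same type on one branch count separately).  A branch is a
"high-confidence" transition if events occur on it in at least 50% of
iterations (inclusive threshold, configurable); it is labelled with its most
frequent destination state.  Per-branch occupancies are mean time-in-state
fractions.

## Comparing bones

Per-iteration total transition counts of the two bones are compared with a
two-sided Wilcoxon rank-sum test (scipy Mann–Whitney backend; exact
enumeration when both samples are tie-free and smaller than 20, otherwise the
normal approximation with tie and continuity corrections).  Transition ages
are pooled across bones with iterations paired by index and analysed with the
random-intercept model age = β₀ + β₁·I(bone) + u_iter + ε, u_iter ~ N(0, σ_u²),
ε ~ N(0, σ²), fit by maximum likelihood (not REML, because the LRT is on a
fixed effect).  The likelihood is profiled: for a given variance ratio
γ = σ_u²/σ², GLS and σ̂² are closed-form via per-group Woodbury identities,
and γ is optimized by bounded scalar search on log γ (tolerance 1e-10 on the
deviance) with the γ = 0 boundary checked explicitly.  The LRT statistic
(deviance difference against the β₁-free model) is referred to chi-square
with 1 df.  The fit is verified in tests against a direct multivariate-normal
deviance evaluation and against statsmodels MixedLM (whose optimizer
occasionally fails to converge on these designs; the test asserts our
deviance is never worse).

## Coefficient-of-variation suite

For a group (n, x̄, s): CV = s/x̄, SE = CV/√(2n).  The Feltz–Miller test
pools CVs with n_i − 1 weights and refers
Σ(n_i−1)(CV_i−CV_p)²/[CV_p²(0.5+CV_p²)] to chi-square with k − 1 df.

The modified signed-likelihood-ratio (MSLR) test computes the normal-model
LRT for a common CV — the constrained optimum profiles the group means
(each μ̂_i(τ) is the positive root of τ²μ² + x̄μ − ((n−1)s²/n + x̄²)) and
maximizes over τ numerically — and calibrates it with a Bartlett-type
correction: the statistic is the LRT divided by its null mean, estimated from
nr seeded Monte-Carlo replicates of the sufficient statistics (x̄_i, s_i²)
at the constrained fit, and referred to chi-square with k − 1 df.  Default
nr = 10,000 gives a relative Monte-Carlo error of about 1.4% on the
statistic; published values of this test typically carry several percent of
the same simulation noise from smaller defaults, which bounds how closely two
implementations can be expected to agree.  The simulation is vectorized
(golden-section search over τ across all replicates at once).

`min_sample_size` holds each sex's CV fixed at its unrounded s/x̄, sets both
sexes to a common n, and returns the smallest n (from 2, cap 1e6) with
asymptotic-test p strictly below α.  With equal weights the statistic is
(n−1)·c with c independent of n, so the scan starts from the closed-form
candidate and verifies minimality.  For the 13-species table this reproduces
the published 5/9/13/21/44; for the Weddell seal it gives 511 against a
published 512 — the published escalation rule for very unequal starting
sample sizes is not stated, and the one-unit discrepancy is left as is.
In the batch table, the minimum n is reported only for species where neither
test is significant at α, matching the published table's convention.

## Phylogenetic paired t-test

Per-species differences d (female CV − male CV) follow
d ~ N(μ·1, σ²·C(λ)), where C is the Brownian-motion covariance (shared
root-to-MRCA path lengths) and λ rescales its off-diagonals.  (μ, σ², λ) are
estimated by joint ML — μ and σ² in closed form by GLS, λ by bounded search
on [0, 1] (tolerance 1e-8), with both boundary values checked.
t = μ̂/SE(μ̂) with SE = √(RSS_GLS/(n−1)/1ᵀC(λ̂)⁻¹1) and two-sided p on
n − 3 df (three estimated parameters).  The unbiased (n − 1) scale in the SE
makes the test collapse exactly to the ordinary one-sample t statistic on a
star phylogeny; the reference R implementation uses the ML scale instead
(ratio √(n/(n−1)), about 4% at n = 13) — its μ̂, λ̂ and log-likelihood are
matched to ≤1e-4 in a frozen-oracle test.

## Synthetic data: what it emulates, and what it does not

`simulate_yule_tree` grows a pure-birth tree to exactly n tips (one final
exponential extension keeps terminal branches positive) and rescales it to a
target depth, 100 My by default, so age summaries are in realistic units.
`simulate_mk_forward` is exact Gillespie simulation; its histories satisfy
the same structural invariants as mapped histories and feed the same
summaries.  `simulate_paired_bones` evolves the two bones independently —
male bone loss-dominated (defaults: loss 0.004/My, gain 0.001/My; losses of
the male bone are rarely reversed), female bone freely labile (0.016/My both
ways; a 4:1 female:male loss-rate ratio) — then applies two observation-level
rules: where the male bone is absent at a tip the female bone is recorded
absent (the empirical one-way coupling), and a present female bone is
recorded polymorphic with probability 0.12 (matching the observed fraction of
polymorphic scores among present-state females).  Measurement groups are
plain normals with sd = CV·mean; negative values are allowed (the CV tests
assume normality), but a specification putting ≥50% of the mass below zero is
rejected.

Two limitations matter when reading test results.  First, complete Yule trees
concentrate branch length near the present, whereas real comparative trees —
a sparse sample of species from a large radiation — carry much of their
length deep in time; consequences for transition-age comparisons are noted
below.  Second, tip data lose information about the number of changes once
rate × depth grows past ~1 (mapped counts estimate what the tips support,
not the true history), so simulation experiments here are designed at
rate × depth ≤ 1.6.

## Design notes on the acceptance-scale experiments

* Rate-recovery simulations (500 tips, ER rate 0.05/My) use depth 20 My so
  that rate × depth = 1, the same per-lineage saturation as the labile bone
  in the comparative data; recovery of the generating rate within 25%
  succeeds in ≥90% of replicates there, while heavily saturated designs fail
  for information-theoretic reasons, not estimator defects.
* Under a time-homogeneous Mk process the true transition ages of a fast and
  a slow trait have the same branch-length-weighted distribution, so the
  synthetic pipeline reproduces "the labile bone has more transitions"
  robustly, but "its transitions are more recent" only for favourable tip
  configurations (empirically about half of datasets; mapping in fact biases
  the labile bone's ages slightly older, because its unforced state churn
  falls on long, deep branches).  Reproducing the recency signal requires the
  empirical tree shape and the clade-clustered losses of the real male-bone
  data; the corresponding acceptance check is therefore expected to fail on
  some synthetic datasets, and does at the committed seed.
* Type-I calibrations: mixed-model LRT at 200 iterations × 3 events per bone
  (σ_u = 2, σ = 5), 500 replicates; Feltz–Miller at n = 50 per group and
  MSLR at n = 200 per group (internal nr = 2,000), 2,000 replicates each.
  All hold 3.5–6.5% rejection at nominal 5%.

## Known limitations

* No Bayesian (MCMC) integration over Q; mapping uncertainty is conditional
  on the ML rates.
* The MSLR statistic inherits seeded Monte-Carlo error (~1.4% at default nr);
  p-values near a decision boundary should be read accordingly.
* No NEXUS input; no fossilized birth–death or trait-dependent
  diversification in the generators; CV tests assume normal measurements.
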