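# Methods

## Model

Each person `i` performs `R` dichotomous trials in each of `J` experimental
conditions. Counts are modeled as independent binomials,
`x_j^i ~ Binomial(R, π_j^i)`, with the person's own success-probability
vector `π^i = (π_1^i, …, π_J^i)`. The prior on `π^i` is the product of
independent uniform Beta(1, 1) laws, which is (a) conjugate, so the
posterior factors into independent Beta(x_j + 1, R − x_j + 1) laws, and (b)
exchangeable across conditions, so hypotheses that are permutations of one
another receive equal prior mass (unbiased complexities). Persons are
analyzed separately — there is deliberately no hierarchical pooling, because
the question is whether a hypothesis holds for *each* person, not on
average.

An informative hypothesis is a set of strict linear inequalities
`H_m: R_m π^i > 0` with a K × J constraint matrix `R_m`. Chains written in
the constraint mini-language (`a > b > c`) expand to adjacent-pair rows
only; implied inequalities are not added, so a full ordering of J conditions
has K = J − 1 rows. The complement of `H_m` is its logical negation.

## Bayes factors

Against the unconstrained (encompassing) hypothesis `H_u`,

* complexity `c_m` = prior mass of the constrained region,
* fit `f_m` = posterior mass of the constrained region,
* `BF_mu = f_m / c_m`, `BF_mm' = BF_mu / BF_m'u`, and against the complement
  `BF_mc = (f_m / c_m) / ((1 − f_m) / (1 − c_m))`.

Because prior and posterior both factor into independent Betas, both masses
are estimated by **direct Monte Carlo**: sample an N × J pool, count the
fraction of draws satisfying all rows. This is exact sampling from the
target distributions, so no MCMC machinery is used or needed. Every
proportion is reported with its binomial standard error `√(p(1−p)/N)`, and
Bayes factors carry a delta-method propagated SE. The default pool size is
N = 10⁶ per person (SE ≈ 5·10⁻⁴ at p = .5), configurable down to 10³ in the
CLI.

Numerical conventions:

* **Shared pools.** All hypotheses in a set are evaluated on the same prior
  pool and the same posterior pool. This makes the pairwise identity
  `BF_mm' = BF_mu / BF_m'u` hold exactly in output and reduces Monte-Carlo
  noise in ratios.
* **Boundary.** Rows are strict. A draw with any row product exactly 0
  satisfies neither the hypothesis nor its complement under the membership
  predicate (a probability-zero event for continuous Betas); in pool
  counting the complement fraction is computed as `1 − f`, assigning any
  boundary hit to the complement so that `f + f_complement = 1` exactly.
* **Analytic shortcut.** For a complete simple ordering of all J conditions
  the complexity is exactly `1/J!` by exchangeability; the analytic value is
  attached to the estimate and preferred in Bayes-factor computation. No
  analytic value is claimed for other constraint shapes (e.g. the
  averages contrast, whose complexity of .5 follows from symmetry but is
  estimated by MC like any other).
* **Degenerate estimates.** A fit of exactly 0 at pool resolution yields
  BF = 0 with a flag (smallest representable nonzero fit is 1/N); no
  pseudo-count correction is invented. A fit of exactly 1 yields an infinity
  sentinel with a warning for the complement BF. A complexity of 0 is an
  error (the hypothesis was never sampled; increase N).

## Best-hypothesis rule

`H_m` is selected for a person when `BF_mm' ≥ max(M − 1, 2)` for every rival
`m'`, which guarantees posterior probability ≥ .5 for the winner under equal
prior odds. The threshold is exposed as a configuration knob since it is one
reasonable convention among several.

## Aggregation across persons

For one fixed comparison, the per-person Bayes factors combine into
`P-BF = ∏ BF^i` (computed in log space; any zero annihilates), the geometric
mean `gP-BF = (P-BF)^(1/P)`, the evidence rate ER (fraction of per-person
BFs on the gP-BF's side of 1) and the stability rate SR (fraction strictly
more extreme than the gP-BF on its side). When gP-BF = 1 exactly, ER and SR
are undefined and returned as an explicit `None` with a flag. Comparisons
are never mixed: statistics for m-vs-u are not translated into
m-vs-complement.

Two practical conventions:

* **Ties.** ER/SR use strict inequalities; a BF exactly equal to 1 (or to
  the gP-BF) counts for neither side. Equality with the gP-BF is judged up
  to a 10⁻¹² relative tolerance because `exp(mean(log x))` of identical
  values can differ from `x` by one ulp, which would otherwise flip SR from
  0 to 1 on a degenerate pool.
* **Censored inputs.** Published BF tables sometimes print small entries as
  bounds ("< 0.01"). These are ingested with a censoring annotation: the
  bound value enters the geometric mean (the result is flagged as an upper
  bound) and ER counting uses the side the bound implies. A censored column
  can place the recomputed geometric mean on the wrong side of 1 relative
  to the value computed from unrounded data; for that reason
  `evidence_rate`/`stability_rate` accept the direction-giving geometric
  mean as an explicit argument, and the published group summary of the
  bundled 26-person table is shipped alongside it as reference data.

## Design analysis

To choose `P` and `R` before data collection, candidate populations are
simulated: the hypothesis true for everyone (`π^i` drawn from the prior
truncated to the constrained region), false for everyone (truncated to the
complement), or a θ-mixture (each person's region chosen by a uniform draw
against θ, default .5). For each population and each R, a surrogate pool of
per-person Bayes factors is built by sampling `π^i`, then counts, then the
BF (default comparison: hypothesis vs complement). For each P, 1000 (default)
bootstrap resamples of size P from the surrogate give the 2.5/50/97.5
percentiles of gP-BF, ER and SR; cells are flagged when the median ER
reaches .9 and the median SR lies within .1 of .5. The full-scale defaults
are a surrogate of 10,000 persons and 1000 bootstrap sets; the bundled
tests and the reproduction script run desk-scale versions (surrogate
1000–2000, 200 sets, per-person pools of 5·10⁴–10⁵, J = 8, R = 21, P = 30),
which already reproduce the qualitative behavior: near-perfect ER and large
gP-BF when the ordering holds for everyone, gP-BF far below 1 when it holds
for no one, and ER near .5 under the θ = .5 mixture.

Sampling from truncated priors: for complete simple orderings, J iid
uniforms are sorted into the required order — valid by exchangeability and
acceptance-free even at J = 8, where plain rejection would accept 1 draw in
40,320. Arbitrary constraint matrices use batched rejection sampling with an
adaptive batch size and a configurable total budget (exceeding it raises an
error carrying the estimated acceptance rate); complements use plain
rejection (acceptance ≈ 1 − c). A property test checks the sort shortcut
against plain rejection at J = 3. Under the complement population at large
J, most surrogate fits are 0 at pool resolution, so the per-person BFs are 0
sentinels; bootstrap gP-BF medians are then 0, which correctly lands on the
"evidence against" side of 1. Bootstrap resamples whose gP-BF is exactly 1
(possible only through such sentinels) are excluded from ER/SR percentiles
and reported as an undefined rate.

## Randomness and reproducibility

Every entry point takes one root seed; per-purpose and per-person streams
are spawned deterministically from it (`numpy` `SeedSequence`), so repeated
runs are bit-identical and persons' pools are independent. The `evaluate`
CLI writes byte-identical output for identical seeds and configs.

## What the synthetic data do and do not show

The bundled worked examples and the design simulator draw counts from exact
binomials with constant R across conditions and persons, and persons are
exchangeable and independent. Real within-subject data can violate all of
this — trial-order effects, learning/fatigue (non-constant π within a
condition), missing trials (unequal R), and dependence between conditions.
Passing tests therefore demonstrate correctness of the estimators and
aggregation under the stated model, not robustness to those violations.
Other known limitations: equality ("about equal") and range constraints are
not supported; hypotheses about the population-average probabilities are out
of scope (the analysis is strictly person-wise); and with small R the
posterior is wide, so per-person Bayes factors are necessarily modest — the
design module exists precisely to quantify that.
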