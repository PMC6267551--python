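"""Complexity, fit, and Bayes factors for order-constrained hypotheses.

For an inequality-constrained hypothesis ``H_m`` evaluated against the
unconstrained hypothesis ``H_u``:

* complexity ``c_m`` is the proportion of the unconstrained (uniform) prior
  in agreement with the constraints,
* fit ``f_m`` is the proportion of the unconstrained posterior in agreement,
* ``BF_mu = f_m / c_m`` and ``BF_mc = (f_m / c_m) / ((1 - f_m) / (1 - c_m))``
  against the complement, and ``BF_mm' = BF_mu / BF_m'u`` pairwise.

Both proportions are estimated by direct Monte Carlo on independent-Beta
draw pools, which is exact for this conjugate model.  All hypotheses in a
set are evaluated on the *same* prior pool and the *same* posterior pool, so
the pairwise ratio identity holds exactly and complement fits satisfy
``f + f_complement = 1`` by construction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .hypotheses import (
    ConditionLayout,
    Hypothesis,
    HypothesisSet,
    complement_of,
    full_ordering_complexity,
)
from .model import (
    BetaProduct,
    DrawPool,
    PersonCounts,
    posterior_update,
    sample_product,
    uniform_prior,
)

__all__ = [
    "MCEstimate",
    "BayesFactor",
    "Decision",
    "PersonEvaluation",
    "EvaluationConfig",
    "estimate_complexity",
    "estimate_fit",
    "bf_vs_unconstrained",
    "bf_vs_complement",
    "bf_pairwise",
    "evaluate_person",
    "evaluate_many",
    "select_best",
]


@dataclass(frozen=True)
class MCEstimate:
    """A Monte-Carlo proportion with its standard error.

    ``analytic`` carries an exact value when one is known (e.g. 1/J! for a
    complete simple ordering under the exchangeable uniform prior); downstream
    Bayes factors prefer it over the sampled value.
    """

    value: float
    std_error: float
    n_draws: int
    analytic: float | None = None

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("a proportion estimate must lie in [0, 1]")
        if self.std_error < 0:
            raise ValueError("standard error must be non-negative")

    @property
    def best(self) -> float:
        """The analytic value when available, else the MC estimate."""
        return self.value if self.analytic is None else self.analytic


def _proportion_estimate(hits: int, n: int, analytic: float | None = None) -> MCEstimate:
    p = hits / n
    return MCEstimate(
        value=p,
        std_error=math.sqrt(p * (1.0 - p) / n),
        n_draws=n,
        analytic=analytic,
    )


@dataclass(frozen=True)
class BayesFactor:
    """A Bayes factor value with a propagated Monte-Carlo standard error."""

    value: float
    std_error: float = 0.0
    flags: tuple[str, ...] = ()

    def __float__(self) -> float:
        return float(self.value)


@dataclass(frozen=True)
class Decision:
    """Outcome of the best-hypothesis rule for one person."""

    best: str | None
    threshold: float

    @property
    def selected(self) -> bool:
        return self.best is not None


@dataclass(frozen=True)
class PersonEvaluation:
    """All estimates and Bayes factors for one person and one hypothesis set."""

    person_id: str
    labels: tuple[str, ...]
    complexity: dict
    fit: dict
    bf_u: dict            # label -> BayesFactor vs unconstrained
    bf_c: dict            # label -> BayesFactor vs complement
    pairwise: dict        # (label, label') -> float, = bf_u[m] / bf_u[m']
    decision: Decision | None = None


@dataclass(frozen=True)
class EvaluationConfig:
    """Monte-Carlo and decision settings for per-person evaluation."""

    n_draws: int = 1_000_000
    seed: int | None = None
    threshold: float | None = None  # None: max(M - 1, 2)


# ---------------------------------------------------------------------------
# Pool-based proportion estimates
# ---------------------------------------------------------------------------

def _informative_hits(h: Hypothesis, draws: np.ndarray) -> int:
    prods = draws @ h.matrix.coefficients.T
    return int(np.count_nonzero(np.all(prods > 0, axis=1)))


def proportion_on_pool(h: Hypothesis, pool: DrawPool) -> MCEstimate:
    """Fraction of a draw pool in agreement with ``h``.

    For a complement hypothesis the fraction is one minus the informative
    fraction on the same pool: boundary draws (any row product exactly zero,
    a probability-zero event) count toward the complement, which keeps
    ``f + f_complement = 1`` exact on shared pools.
    """
    n = pool.n_draws
    if h.kind == "unconstrained":
        return _proportion_estimate(n, n, analytic=1.0)
    base = Hypothesis(h.label, "informative", h.matrix)
    hits = _informative_hits(base, pool.draws)
    if h.kind == "informative":
        analytic = full_ordering_complexity(h) if pool.source == "prior" else None
        return _proportion_estimate(hits, n, analytic=analytic)
    # complement
    analytic = None
    if pool.source == "prior":
        c = full_ordering_complexity(base)
        analytic = None if c is None else 1.0 - c
    return _proportion_estimate(n - hits, n, analytic=analytic)


def estimate_complexity(
    h: Hypothesis, layout: ConditionLayout, n: int = 1_000_000, seed=None
) -> MCEstimate:
    """Complexity: proportion of the uniform prior satisfying ``h``."""
    if h.kind == "unconstrained":
        raise ValueError("complexity is defined relative to the unconstrained prior")
    pool = sample_product(uniform_prior(layout), n, seed, source="prior")
    return proportion_on_pool(h, pool)


def estimate_fit(
    h: Hypothesis, posterior: BetaProduct, n: int = 1_000_000, seed=None
) -> MCEstimate:
    """Fit: proportion of the unconstrained posterior satisfying ``h``."""
    if h.kind == "unconstrained":
        raise ValueError("fit is defined relative to the unconstrained posterior")
    pool = sample_product(posterior, n, seed, source="posterior")
    return proportion_on_pool(h, pool)


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------

def _as_estimate(x) -> tuple[float, float]:
    if isinstance(x, MCEstimate):
        return x.best, (0.0 if x.analytic is not None else x.std_error)
    return float(x), 0.0


def bf_vs_unconstrained(fit, complexity) -> BayesFactor:
    """``BF_mu = f / c``: relative belief change for H_m versus H_u."""
    f, se_f = _as_estimate(fit)
    c, se_c = _as_estimate(complexity)
    if c <= 0.0:
        raise ValueError(
            "complexity estimate is zero: the hypothesis region was never hit "
            "at this pool size; increase the draw count"
        )
    value = f / c
    flags = ()
    if f == 0.0:
        flags = ("zero_fit",)
    se = value * math.hypot(se_f / f if f > 0 else 0.0, se_c / c)
    return BayesFactor(value=value, std_error=se, flags=flags)


def bf_vs_complement(fit, complexity) -> BayesFactor:
    """``BF_mc = (f/c) / ((1-f)/(1-c))``: H_m versus its complement."""
    f, se_f = _as_estimate(fit)
    c, se_c = _as_estimate(complexity)
    if not 0.0 < c < 1.0:
        raise ValueError("complexity must lie strictly between 0 and 1")
    if f >= 1.0:
        warnings.warn(
            "fit estimate is 1 at this pool size; BF vs complement is "
            "reported as infinity",
            stacklevel=2,
        )
        return BayesFactor(value=math.inf, std_error=math.nan, flags=("fit_one",))
    if f == 0.0:
        return BayesFactor(value=0.0, std_error=0.0, flags=("zero_fit",))
    value = (f / c) / ((1.0 - f) / (1.0 - c))
    # delta method: d(BF)/df = (1-c)/(c (1-f)^2); d(BF)/dc = -f/((1-f) c^2)
    dfd = (1.0 - c) / (c * (1.0 - f) ** 2)
    dcd = -f / ((1.0 - f) * c * c) if se_c else 0.0
    se = math.hypot(dfd * se_f, dcd * se_c)
    return BayesFactor(value=value, std_error=se)


def bf_pairwise(bf_mu, bf_mprime_u) -> float:
    """``BF_mm' = BF_mu / BF_m'u``: marginal-likelihood ratio of two hypotheses."""
    a = float(bf_mu)
    b = float(bf_mprime_u)
    if b == 0.0:
        warnings.warn("denominator Bayes factor is 0; ratio is infinity", stacklevel=2)
        return math.inf if a > 0 else math.nan
    return a / b


# ---------------------------------------------------------------------------
# Per-person evaluation
# ---------------------------------------------------------------------------

def _complexities_on_pool(hset: HypothesisSet, prior_pool: DrawPool) -> dict:
    return {h.label: proportion_on_pool(h, prior_pool) for h in hset.hypotheses}


def _evaluate_with_pools(
    data: PersonCounts,
    hset: HypothesisSet,
    complexities: dict,
    posterior_pool: DrawPool,
    threshold: float | None,
) -> PersonEvaluation:
    fits = {h.label: proportion_on_pool(h, posterior_pool) for h in hset.hypotheses}
    bf_u = {m: bf_vs_unconstrained(fits[m], complexities[m]) for m in fits}
    bf_c = {m: bf_vs_complement(fits[m], complexities[m]) for m in fits}
    labels = tuple(hset.labels)
    pairwise = {
        (m, mp): bf_pairwise(bf_u[m], bf_u[mp])
        for m in labels
        for mp in labels
    }
    ev = PersonEvaluation(
        person_id=data.person_id,
        labels=labels,
        complexity=complexities,
        fit=fits,
        bf_u=bf_u,
        bf_c=bf_c,
        pairwise=pairwise,
    )
    decision = select_best(ev, threshold=threshold) if len(labels) >= 2 else None
    return replace(ev, decision=decision)


def evaluate_person(
    data: PersonCounts,
    hset: HypothesisSet,
    config: EvaluationConfig = EvaluationConfig(),
) -> PersonEvaluation:
    """Evaluate all hypotheses in a set for one person.

    Complexities are estimated on one shared uniform-prior pool and fits on
    one shared posterior pool, so pairwise Bayes factors equal the exact
    ratios of the stored ``BF_mu`` values.
    """
    if data.layout.n_conditions != hset.layout.n_conditions:
        raise ValueError("data and hypothesis set layouts disagree")
    ss = np.random.SeedSequence(config.seed)
    prior_seed, post_seed = ss.spawn(2)
    prior_pool = sample_product(
        uniform_prior(hset.layout), config.n_draws, np.random.default_rng(prior_seed),
        source="prior",
    )
    complexities = _complexities_on_pool(hset, prior_pool)
    posterior = posterior_update(uniform_prior(hset.layout), data)
    posterior_pool = sample_product(
        posterior, config.n_draws, np.random.default_rng(post_seed), source="posterior"
    )
    return _evaluate_with_pools(data, hset, complexities, posterior_pool, config.threshold)


def evaluate_many(
    persons: list[PersonCounts],
    hset: HypothesisSet,
    config: EvaluationConfig = EvaluationConfig(),
) -> list[PersonEvaluation]:
    """Evaluate a hypothesis set for several persons.

    One prior pool is shared by all persons (complexity does not depend on
    the data); each person gets an independent, deterministically derived
    posterior sampling stream.
    """
    if not persons:
        raise ValueError("no persons to evaluate")
    ss = np.random.SeedSequence(config.seed)
    prior_seed, *person_seeds = ss.spawn(1 + len(persons))
    prior_pool = sample_product(
        uniform_prior(hset.layout), config.n_draws, np.random.default_rng(prior_seed),
        source="prior",
    )
    complexities = _complexities_on_pool(hset, prior_pool)
    prior = uniform_prior(hset.layout)
    out = []
    for person, child in zip(persons, person_seeds):
        posterior = posterior_update(prior, person)
        pool = sample_product(
            posterior, config.n_draws, np.random.default_rng(child), source="posterior"
        )
        out.append(
            _evaluate_with_pools(person, hset, complexities, pool, config.threshold)
        )
    return out


def select_best(ev: PersonEvaluation, threshold: float | None = None) -> Decision:
    """Best-hypothesis rule: H_m is selected when its Bayes factor is at least
    ``max(M - 1, 2)`` times the Bayes factor of every other hypothesis.

    The default threshold guarantees a posterior probability of at least .5
    for the selected hypothesis under equal prior odds; it can be overridden.
    """
    m_count = len(ev.labels)
    if m_count < 2:
        raise ValueError("the selection rule needs at least two hypotheses")
    thr = float(threshold) if threshold is not None else float(max(m_count - 1, 2))
    for m in ev.labels:
        if all(ev.pairwise[(m, mp)] >= thr for mp in ev.labels if mp != m):
            return Decision(best=m, threshold=thr)
    return Decision(best=None, threshold=thr)
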