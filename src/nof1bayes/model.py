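"""Conjugate Beta-binomial machinery for one person's within-subject data.

Each person performs R dichotomous trials in each of J conditions; the count
of successes per condition is binomial with unknown success probability.
With independent uniform Beta(1, 1) priors the posterior factors into
independent Beta(x_j + 1, R - x_j + 1) laws, so prior and posterior vectors
can be sampled directly and exactly (no MCMC needed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hypotheses import ConditionLayout

__all__ = [
    "PersonCounts",
    "BetaProduct",
    "DrawPool",
    "uniform_prior",
    "posterior_update",
    "sample_product",
    "simulate_counts",
]


def as_generator(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence, or Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class PersonCounts:
    """Success counts of one person: x_j in {0..R} for each condition j."""

    person_id: str
    successes: np.ndarray
    layout: ConditionLayout

    def __init__(self, person_id, successes: Sequence[int], layout: ConditionLayout):
        x = np.asarray(successes)
        if x.shape != (layout.n_conditions,):
            raise ValueError(
                f"expected {layout.n_conditions} counts, got shape {x.shape}"
            )
        if not np.issubdtype(x.dtype, np.integer):
            if not np.all(x == np.floor(x)):
                raise ValueError("success counts must be integers")
            x = x.astype(int)
        if np.any(x < 0) or np.any(x > layout.replications):
            raise ValueError(
                f"success counts must lie in [0, {layout.replications}]"
            )
        x = x.copy()
        x.setflags(write=False)
        object.__setattr__(self, "person_id", str(person_id))
        object.__setattr__(self, "successes", x)
        object.__setattr__(self, "layout", layout)


@dataclass(frozen=True)
class BetaProduct:
    """J independent Beta(alpha_j, beta_j) laws (a prior or posterior on pi)."""

    alphas: np.ndarray
    betas: np.ndarray

    def __init__(self, alphas, betas):
        a = np.asarray(alphas, dtype=float)
        b = np.asarray(betas, dtype=float)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("alphas and betas must be 1-D arrays of equal length")
        if np.any(a <= 0) or np.any(b <= 0):
            raise ValueError("Beta parameters must be strictly positive")
        a = a.copy(); a.setflags(write=False)
        b = b.copy(); b.setflags(write=False)
        object.__setattr__(self, "alphas", a)
        object.__setattr__(self, "betas", b)

    @property
    def n_conditions(self) -> int:
        return len(self.alphas)

    @property
    def means(self) -> np.ndarray:
        return self.alphas / (self.alphas + self.betas)


@dataclass(frozen=True)
class DrawPool:
    """An N x J pool of sampled probability vectors with its provenance."""

    draws: np.ndarray
    seed: object
    source: str  # "prior" | "posterior"

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def uniform_prior(layout: ConditionLayout) -> BetaProduct:
    """The uniform Beta(1, 1) product prior on (0, 1)^J."""
    j = layout.n_conditions
    return BetaProduct(np.ones(j), np.ones(j))


def posterior_update(prior: BetaProduct, data: PersonCounts) -> BetaProduct:
    """Conjugate update: alpha_1 = x_j + alpha_0, beta_1 = (R - x_j) + beta_0."""
    if prior.n_conditions != data.layout.n_conditions:
        raise ValueError("prior and data dimension mismatch")
    r = data.layout.replications
    return BetaProduct(
        prior.alphas + data.successes,
        prior.betas + (r - data.successes),
    )


def sample_product(bp: BetaProduct, n: int, seed, source: str = "posterior") -> DrawPool:
    """Sample an N x J pool of independent draws, column j ~ Beta(a_j, b_j)."""
    if n < 1:
        raise ValueError("draw count must be at least 1")
    rng = as_generator(seed)
    draws = rng.beta(bp.alphas, bp.betas, size=(int(n), bp.n_conditions))
    return DrawPool(draws=draws, seed=seed, source=source)


def simulate_counts(
    pi: Sequence[float],
    layout: ConditionLayout,
    seed,
    person_id: str = "sim",
) -> PersonCounts:
    """Simulate one person's counts: x_j ~ Binomial(R, pi_j) independently."""
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (layout.n_conditions,):
        raise ValueError("probability vector length must equal J")
    if np.any(pi < 0) or np.any(pi > 1):
        raise ValueError("success probabilities must lie in [0, 1]")
    rng = as_generator(seed)
    x = rng.binomial(layout.replications, pi)
    return PersonCounts(person_id, x, layout)
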