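"""Simulation-based design analysis for choosing P (persons) and R (replications).

For a hypothesis of interest, candidate populations are specified in which
the hypothesis is true for everyone, false for everyone (the complement), or
true for a proportion theta of persons.  For each population and each R, a
large surrogate pool of per-person Bayes factors is simulated:

1. draw a probability vector ``pi`` from the uniform prior truncated to the
   population's region,
2. sample counts ``x_j ~ Binomial(R, pi_j)``,
3. compute the person's Bayes factor for the configured comparison
   (default: hypothesis versus its complement).

For each candidate sample size P, sets of P Bayes factors are then drawn
with replacement from the surrogate and the gP-BF, evidence rate, and
stability rate are computed per set; their 2.5/50/97.5 percentiles summarize
what a study of that size can expect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .aggregate import BFVector, evidence_rate, gp_bf, stability_rate
from .hypotheses import (
    ConditionLayout,
    Hypothesis,
    full_ordering_complexity,
    full_ordering_permutation,
    membership,
)
from .model import as_generator, sample_product, uniform_prior

__all__ = [
    "PopulationSpec",
    "DesignConfig",
    "DesignCell",
    "DesignResult",
    "RejectionBudgetError",
    "sample_wp_population",
    "sample_wp_populations",
    "build_surrogate",
    "bootstrap_design",
    "run_design",
]


class RejectionBudgetError(RuntimeError):
    """Rejection sampling exhausted its draw budget."""


@dataclass(frozen=True)
class PopulationSpec:
    """A hypothetical P-population for the design analysis.

    mode ``"under_h"``: the hypothesis is true for every person (prior
    truncated to its region); ``"under_complement"``: false for everyone;
    ``"mixture"``: true for a proportion ``theta`` of persons.
    """

    hypothesis: Hypothesis
    mode: str
    theta: float | None = None

    def __post_init__(self):
        if self.mode not in ("under_h", "under_complement", "mixture"):
            raise ValueError(f"unknown population mode: {self.mode!r}")
        if self.mode == "mixture":
            if self.theta is None or not 0.0 <= self.theta <= 1.0:
                raise ValueError("mixture mode requires theta in [0, 1]")
        elif self.theta is not None:
            raise ValueError("theta is only meaningful in mixture mode")

    @property
    def label(self) -> str:
        if self.mode == "mixture":
            return f"mixture(theta={self.theta})"
        return self.mode


@dataclass(frozen=True)
class DesignConfig:
    """Grids and Monte-Carlo sizes for a design analysis run.

    The documented full-scale defaults are a surrogate of 10,000 persons and
    1000 bootstrap sets per cell; desk-scale runs may reduce both.
    ``n_draws`` is the per-person posterior pool used for each surrogate
    Bayes factor.
    """

    layout: ConditionLayout
    populations: tuple[PopulationSpec, ...]
    r_grid: tuple[int, ...]
    p_grid: tuple[int, ...]
    surrogate_size: int = 10_000
    bootstrap_sets: int = 1000
    percentiles: tuple[float, ...] = (2.5, 50.0, 97.5)
    n_draws: int = 100_000
    seed: int | None = None
    comparison: str = "vs_complement"  # or "vs_unconstrained"
    er_threshold: float = 0.9
    sr_margin: float = 0.1
    rejection_budget: int = 10_000_000

    def __post_init__(self):
        if not self.r_grid or not self.p_grid:
            raise ValueError("R and P grids must be non-empty")
        if any(r < 1 for r in self.r_grid) or any(p < 1 for p in self.p_grid):
            raise ValueError("grid entries must be positive")
        if self.surrogate_size < max(self.p_grid):
            raise ValueError("surrogate size must be at least the largest P")
        if any(not 0.0 < q < 100.0 for q in self.percentiles):
            raise ValueError("percentiles must lie in (0, 100)")
        if self.comparison not in ("vs_complement", "vs_unconstrained"):
            raise ValueError(f"unsupported design comparison: {self.comparison!r}")


@dataclass(frozen=True)
class DesignCell:
    """Percentile summaries for one (population, R, P) cell."""

    population: str
    r: int
    p: int
    percentiles: tuple[float, ...]
    gp_bf: tuple[float, ...]
    er: tuple[float, ...]
    sr: tuple[float, ...]
    er_undefined_rate: float
    sr_undefined_rate: float
    meets_er: bool
    meets_sr: bool


@dataclass(frozen=True)
class DesignResult:
    """Full grid of design-analysis summaries."""

    cells: tuple[DesignCell, ...]
    config: DesignConfig

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: population, R, P, statistic, percentile, value."""
        rows = []
        for cell in self.cells:
            for stat, trip in (("gp_bf", cell.gp_bf), ("er", cell.er), ("sr", cell.sr)):
                for q, val in zip(cell.percentiles, trip):
                    rows.append(
                        {
                            "population": cell.population,
                            "R": cell.r,
                            "P": cell.p,
                            "statistic": stat,
                            "percentile": q,
                            "value": val,
                        }
                    )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Truncated-prior sampling
# ---------------------------------------------------------------------------

def _sample_ordering(perm: Sequence[int], n: int, j: int, rng) -> np.ndarray:
    """Sort-based sampler for a complete simple ordering.

    By exchangeability of the uniform prior, sorting J iid uniforms and
    assigning them along the required permutation samples exactly from the
    truncated prior — with no rejections, even at J = 8 where plain
    rejection would accept 1 draw in 40,320.
    """
    u = rng.random((n, j))
    u.sort(axis=1)
    out = np.empty((n, j))
    out[:, list(perm)] = u[:, ::-1]
    return out


def _sample_rejection(h: Hypothesis, region: str, n: int, j: int, rng,
                      budget: int) -> np.ndarray:
    """Batched rejection sampling from the prior truncated to a region."""
    test = Hypothesis(h.label, region, h.matrix)
    kept: list[np.ndarray] = []
    total_drawn = 0
    total_kept = 0
    batch = max(4 * n, 1024)
    while total_kept < n:
        if total_drawn >= budget:
            rate = total_kept / total_drawn if total_drawn else 0.0
            raise RejectionBudgetError(
                f"rejection budget of {budget} draws exhausted; estimated "
                f"acceptance rate {rate:.2e} — use a sort-based sampler or a "
                f"larger budget"
            )
        batch = min(batch, budget - total_drawn)
        candidates = rng.random((batch, j))
        ok = membership(test, candidates)
        kept.append(candidates[ok])
        total_kept += int(ok.sum())
        total_drawn += batch
        accept = max(total_kept / total_drawn, 1.0 / total_drawn)
        batch = int(min(max((n - total_kept) / accept * 1.2, 1024), 2_000_000))
    return np.concatenate(kept)[:n]


def sample_wp_populations(
    spec: PopulationSpec,
    layout: ConditionLayout,
    n: int,
    seed,
    budget: int = 10_000_000,
) -> np.ndarray:
    """Sample ``n`` probability vectors from the truncated prior of a population."""
    rng = as_generator(seed)
    j = layout.n_conditions
    h = spec.hypothesis
    if spec.mode == "mixture":
        u = rng.random(n)
        in_h = u <= spec.theta
        out = np.empty((n, j))
        n_h = int(in_h.sum())
        if n_h:
            out[in_h] = sample_wp_populations(
                PopulationSpec(h, "under_h"), layout, n_h, rng, budget
            )
        if n - n_h:
            out[~in_h] = sample_wp_populations(
                PopulationSpec(h, "under_complement"), layout, n - n_h, rng, budget
            )
        return out
    if spec.mode == "under_h":
        perm = full_ordering_permutation(h)
        if perm is not None:
            return _sample_ordering(perm, n, j, rng)
        return _sample_rejection(h, "informative", n, j, rng, budget)
    return _sample_rejection(h, "complement", n, j, rng, budget)


def sample_wp_population(spec: PopulationSpec, layout: ConditionLayout, seed) -> np.ndarray:
    """Sample a single probability vector (see :func:`sample_wp_populations`)."""
    return sample_wp_populations(spec, layout, 1, seed)[0]


# ---------------------------------------------------------------------------
# Surrogate population of Bayes factors
# ---------------------------------------------------------------------------

def _complexity_for_design(h: Hypothesis, layout: ConditionLayout, n_draws: int,
                           rng) -> float:
    c = full_ordering_complexity(h)
    if c is not None:
        return c
    pool = sample_product(uniform_prior(layout), n_draws, rng, source="prior")
    prods = pool.draws @ h.matrix.coefficients.T
    c = float(np.mean(np.all(prods > 0, axis=1)))
    if c == 0.0:
        raise ValueError(
            "complexity estimate is zero at this pool size; increase n_draws"
        )
    return c


def build_surrogate(
    spec: PopulationSpec,
    layout: ConditionLayout,
    r: int,
    size: int,
    seed,
    n_draws: int = 100_000,
    comparison: str = "vs_complement",
    budget: int = 10_000_000,
) -> np.ndarray:
    """Simulate a surrogate pool of per-person Bayes factors at replication R.

    Returns ``size`` Bayes factors for the configured comparison.  A fit of
    exactly 0 yields BF 0 and a fit of exactly 1 yields BF infinity when
    comparing against the complement; both reflect the resolution limit of
    the per-person pool and survive into the bootstrap untouched.
    """
    rng = as_generator(seed)
    h = spec.hypothesis
    coef_t = h.matrix.coefficients.T
    c = _complexity_for_design(h, layout, n_draws, rng)
    pis = sample_wp_populations(spec, layout, size, rng, budget)
    counts = rng.binomial(r, pis)
    alphas = counts + 1.0
    betas = (r - counts) + 1.0
    bfs = np.empty(size)
    for i in range(size):
        draws = rng.beta(alphas[i], betas[i], size=(n_draws, layout.n_conditions))
        f = np.count_nonzero(np.all(draws @ coef_t > 0, axis=1)) / n_draws
        if comparison == "vs_unconstrained":
            bfs[i] = f / c
        else:
            if f >= 1.0:
                bfs[i] = math.inf
            else:
                bfs[i] = (f / c) / ((1.0 - f) / (1.0 - c))
    return bfs


# ---------------------------------------------------------------------------
# Bootstrap summaries
# ---------------------------------------------------------------------------

def _percentile_triplet(values: np.ndarray, qs: Sequence[float]) -> tuple[float, ...]:
    if len(values) == 0:
        return tuple(math.nan for _ in qs)
    return tuple(float(q) for q in np.percentile(values, list(qs)))


def bootstrap_design(
    surrogate: np.ndarray,
    p: int,
    sets: int,
    seed,
    percentiles: Sequence[float] = (2.5, 50.0, 97.5),
) -> dict:
    """Bootstrap gP-BF / ER / SR percentiles at sample size P.

    ``sets`` resamples of size P are drawn with replacement from the
    surrogate pool; the three statistics are computed per resample and the
    requested percentiles of each are returned.  Resamples whose gP-BF is
    exactly 1 leave ER and SR undefined; these are excluded from the ER/SR
    percentiles and reported as an undefined rate.
    """
    if p < 1 or sets < 1:
        raise ValueError("P and the number of bootstrap sets must be positive")
    rng = as_generator(seed)
    surrogate = np.asarray(surrogate, dtype=float)
    idx = rng.integers(0, len(surrogate), size=(sets, p))
    samples = surrogate[idx]
    gps = np.empty(sets)
    ers = np.full(sets, np.nan)
    srs = np.full(sets, np.nan)
    for s in range(sets):
        vec = BFVector(samples[s], comparison="bootstrap")
        g = gp_bf(vec)
        gps[s] = g
        er = evidence_rate(vec, g)
        sr = stability_rate(vec, g)
        if er is not None:
            ers[s] = er
        if sr is not None:
            srs[s] = sr
    er_def = ers[~np.isnan(ers)]
    sr_def = srs[~np.isnan(srs)]
    return {
        "gp_bf": _percentile_triplet(gps, percentiles),
        "er": _percentile_triplet(er_def, percentiles),
        "sr": _percentile_triplet(sr_def, percentiles),
        "er_undefined_rate": float(np.mean(np.isnan(ers))),
        "sr_undefined_rate": float(np.mean(np.isnan(srs))),
    }


def run_design(config: DesignConfig) -> DesignResult:
    """Run the full design grid: populations x R (surrogates) x P (bootstrap).

    Within one (population, R) cell a single surrogate pool is shared across
    the whole P grid; the bootstrap then varies only the sample size.  Cells
    are flagged when their median ER reaches ``er_threshold`` and their
    median SR lies within ``sr_margin`` of .5.
    """
    ss = np.random.SeedSequence(config.seed)
    cells: list[DesignCell] = []
    med_index = _median_index(config.percentiles)
    for spec in config.populations:
        for r in config.r_grid:
            child = ss.spawn(2)
            surrogate = build_surrogate(
                spec,
                config.layout,
                r,
                config.surrogate_size,
                np.random.default_rng(child[0]),
                n_draws=config.n_draws,
                comparison=config.comparison,
                budget=config.rejection_budget,
            )
            boot_rng = np.random.default_rng(child[1])
            for p in config.p_grid:
                stats = bootstrap_design(
                    surrogate, p, config.bootstrap_sets, boot_rng,
                    percentiles=config.percentiles,
                )
                med_er = stats["er"][med_index] if med_index is not None else math.nan
                med_sr = stats["sr"][med_index] if med_index is not None else math.nan
                cells.append(
                    DesignCell(
                        population=spec.label,
                        r=r,
                        p=p,
                        percentiles=tuple(config.percentiles),
                        gp_bf=stats["gp_bf"],
                        er=stats["er"],
                        sr=stats["sr"],
                        er_undefined_rate=stats["er_undefined_rate"],
                        sr_undefined_rate=stats["sr_undefined_rate"],
                        meets_er=bool(med_er >= config.er_threshold),
                        meets_sr=bool(abs(med_sr - 0.5) <= config.sr_margin),
                    )
                )
    return DesignResult(cells=tuple(cells), config=config)


def _median_index(percentiles: Sequence[float]) -> int | None:
    for i, q in enumerate(percentiles):
        if q == 50.0:
            return i
    return None
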