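"""Group-level aggregation of per-person Bayes factors.

For one fixed comparison (H_m vs H_u, vs H_m', or vs the complement) across
P independent persons:

* P-BF: the product of the individual Bayes factors, the evidence that the
  hypothesis holds for *every* person,
* gP-BF: its P-th root (geometric mean), the Bayes factor expected for the
  next person sampled from the population,
* evidence rate (ER): the proportion of individual Bayes factors on the same
  side of 1 as the gP-BF (homogeneity of the preferred hypothesis),
* stability rate (SR): the proportion of individual Bayes factors strictly
  more extreme than the gP-BF on its side (skewness / influence).

ER and SR are undefined when the gP-BF equals 1 exactly; that case is
returned as ``None`` with a flag rather than silently picking a side.

Published Bayes-factor tables sometimes censor small entries (e.g. printed
as "< 0.01").  Such values are accepted with a censoring annotation: the
bound value enters the geometric mean (flagging the result as a bound) while
ER counting uses the side the bound implies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BFVector",
    "AggregateSummary",
    "p_bf",
    "gp_bf",
    "evidence_rate",
    "stability_rate",
    "aggregate_vector",
    "aggregate",
]


@dataclass(frozen=True)
class BFVector:
    """Per-person Bayes factors for one fixed comparison.

    ``censored`` marks entries recorded as bounds: ``"lt"`` means the true
    value is below the stored bound (printed "< value"), ``"gt"`` above it;
    ``None`` means observed exactly.
    """

    values: np.ndarray
    comparison: str = "vs_unconstrained"
    censored: tuple[str | None, ...] = ()

    def __init__(self, values: Sequence[float], comparison: str = "vs_unconstrained",
                 censored: Sequence[str | None] | None = None):
        v = np.asarray(values, dtype=float)
        if v.ndim != 1 or len(v) < 1:
            raise ValueError("a BF vector needs at least one value")
        if np.any(v < 0) or np.any(np.isnan(v)):
            raise ValueError("Bayes factors must be non-negative numbers")
        cens = tuple(censored) if censored is not None else (None,) * len(v)
        if len(cens) != len(v):
            raise ValueError("censoring annotations must match the value count")
        for c in cens:
            if c not in (None, "lt", "gt"):
                raise ValueError(f"unknown censoring code: {c!r}")
        v = v.copy(); v.setflags(write=False)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "comparison", comparison)
        object.__setattr__(self, "censored", cens)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def has_censoring(self) -> bool:
        return any(c is not None for c in self.censored)


@dataclass(frozen=True)
class AggregateSummary:
    """P-BF, gP-BF, ER and SR for one comparison across P persons."""

    comparison: str
    n_persons: int
    p_bf: float
    gp_bf: float
    er: float | None
    sr: float | None
    flags: tuple[str, ...] = ()


def p_bf(v: BFVector) -> float:
    """Product of the individual Bayes factors (log-space; 0 annihilates)."""
    vals = v.values
    if np.any(vals == 0.0):
        return 0.0
    return float(math.exp(np.sum(np.log(vals))))


def gp_bf(v: BFVector) -> float:
    """Geometric mean of the individual Bayes factors; independent of P."""
    vals = v.values
    if np.any(vals == 0.0):
        return 0.0
    return float(math.exp(np.mean(np.log(vals))))


def _sides(v: BFVector) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (below 1, above 1) honouring censoring bounds.

    An entry censored as "< b" with b <= 1 is certainly below 1; "> b" with
    b >= 1 certainly above.  Bounds that straddle 1 fall back on the bound
    value itself.
    """
    vals = v.values
    below = vals < 1.0
    above = vals > 1.0
    for i, c in enumerate(v.censored):
        if c == "lt" and vals[i] <= 1.0:
            below[i], above[i] = True, False
        elif c == "gt" and vals[i] >= 1.0:
            below[i], above[i] = False, True
    return below, above


def evidence_rate(v: BFVector, gp: float | None = None) -> float | None:
    """Proportion of individual BFs preferring the same hypothesis as the gP-BF.

    If the geometric mean exceeds 1, the fraction of BFs above 1; if it is
    below 1, the fraction below 1; if exactly 1, undefined (``None``).  The
    direction ``gp`` may be supplied externally (e.g. a published geometric
    mean when the inputs themselves are censored bounds).
    """
    g = gp_bf(v) if gp is None else float(gp)
    below, above = _sides(v)
    if g > 1.0:
        return float(np.mean(above))
    if g < 1.0:
        return float(np.mean(below))
    return None


def stability_rate(v: BFVector, gp: float | None = None) -> float | None:
    """Proportion of individual BFs strictly more extreme than the gP-BF.

    Strictly above the geometric mean when it exceeds 1, strictly below when
    it is below 1, undefined when it equals 1 exactly.  Values equal to the
    geometric mean count for neither side; equality is judged up to a 1e-12
    relative tolerance so that round-off in the log-space geometric mean
    cannot turn a degenerate pool of identical Bayes factors into "all above".
    """
    g = gp_bf(v) if gp is None else float(gp)
    vals = v.values
    tol = 1e-12 * abs(g)
    if g > 1.0:
        return float(np.mean(vals > g + tol))
    if g < 1.0:
        return float(np.mean(vals < g - tol))
    return None


def aggregate_vector(v: BFVector) -> AggregateSummary:
    """Compute all four statistics for one BF vector."""
    g = gp_bf(v)
    flags: list[str] = []
    if np.any(v.values == 0.0):
        flags.append("zero_bf_present")
    if g == 1.0:
        flags.append("gp_exactly_one")
    if v.has_censoring:
        flags.append("gp_is_bound")
    return AggregateSummary(
        comparison=v.comparison,
        n_persons=len(v),
        p_bf=p_bf(v),
        gp_bf=g,
        er=evidence_rate(v, g),
        sr=stability_rate(v, g),
        flags=tuple(flags),
    )


def _vector_from_evaluations(evaluations, label: str, comparison: str) -> BFVector:
    if comparison == "vs_unconstrained":
        vals = [float(ev.bf_u[label]) for ev in evaluations]
    elif comparison == "vs_complement":
        vals = [float(ev.bf_c[label]) for ev in evaluations]
    elif comparison.startswith("vs_"):
        other = comparison[3:]
        vals = [ev.pairwise[(label, other)] for ev in evaluations]
    else:
        raise ValueError(f"unknown comparison: {comparison!r}")
    return BFVector(vals, comparison=f"{label} {comparison}")


def aggregate(
    evaluations: Sequence,
    comparisons: Iterable[tuple[str, str]],
) -> list[AggregateSummary]:
    """Aggregate per-person evaluations for the requested comparisons.

    ``comparisons`` is a list of ``(label, comparison)`` pairs where
    ``comparison`` is ``"vs_unconstrained"``, ``"vs_complement"`` or
    ``"vs_<other label>"``.  Each comparison is aggregated from its own
    per-person Bayes factors; statistics are never translated from one
    comparison to another.
    """
    evaluations = list(evaluations)
    if not evaluations:
        raise ValueError("no evaluations to aggregate")
    labels = evaluations[0].labels
    for ev in evaluations:
        if ev.labels != labels:
            raise ValueError("evaluations do not share a hypothesis set")
    return [
        aggregate_vector(_vector_from_evaluations(evaluations, label, comp))
        for label, comp in comparisons
    ]
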