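"""Informative hypotheses as linear inequality constraints on success probabilities.

An informative hypothesis ``H_m`` on a vector of condition success
probabilities ``pi = (pi_1, ..., pi_J)`` is written ``R_m pi > 0`` where
``R_m`` is a K x J constraint matrix and the inequality holds row-wise and
strictly.  A full ordering ``pi_1 > pi_2 > pi_3`` is encoded as two adjacent
pairwise rows; averages such as ``(pi_1 + pi_2)/2 > (pi_3 + pi_4)/2`` become a
single row of +-0.5 coefficients.

Hypotheses are typically written in a small constraint mini-language rather
than as raw matrices, e.g.::

    c1 > c2 > c3 > c4
    (c1 + c2)/2 > (c3 + c4)/2
    c1 - c3 > c2 - c4
    c1 > c2; c3 > c4        # ';' separates independent constraint groups

and parsed with :func:`parse_hypothesis`.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConditionLayout",
    "ConstraintMatrix",
    "Hypothesis",
    "HypothesisSet",
    "ConstraintDiagnostics",
    "HypothesisParseError",
    "parse_hypothesis",
    "complement_of",
    "validate_constraints",
    "membership",
    "full_ordering_permutation",
]


class HypothesisParseError(ValueError):
    """Raised when a constraint string cannot be parsed."""


@dataclass(frozen=True)
class ConditionLayout:
    """Experimental layout: J named conditions, R binomial replications each."""

    names: tuple[str, ...]
    replications: int

    def __init__(self, names: Sequence[str], replications: int):
        names = tuple(str(n) for n in names)
        if len(names) < 2:
            raise ValueError("a layout needs at least two conditions")
        if len(set(names)) != len(names):
            raise ValueError("condition names must be unique")
        if any(not n for n in names):
            raise ValueError("condition names must be non-empty")
        if int(replications) < 1:
            raise ValueError("replications must be a positive integer")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "replications", int(replications))

    @property
    def n_conditions(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown condition name: {name!r}") from None


@dataclass(frozen=True)
class ConstraintMatrix:
    """K x J real matrix; each row r encodes the strict inequality r . pi > 0."""

    coefficients: np.ndarray

    def __init__(self, coefficients):
        coef = np.atleast_2d(np.asarray(coefficients, dtype=float))
        if coef.ndim != 2:
            raise ValueError("constraint coefficients must form a 2-D matrix")
        if coef.shape[0] < 1:
            raise ValueError("constraint matrix needs at least one row")
        if np.any(np.all(coef == 0.0, axis=1)):
            raise ValueError("constraint matrix contains an all-zero row")
        coef = coef.copy()
        coef.setflags(write=False)
        object.__setattr__(self, "coefficients", coef)

    @property
    def n_rows(self) -> int:
        return self.coefficients.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.coefficients.shape[1]


@dataclass(frozen=True)
class Hypothesis:
    """A labelled hypothesis: informative, its complement, or unconstrained.

    For ``kind="complement"`` the stored matrix is the matrix of the negated
    informative hypothesis; membership is the logical negation of the
    informative hypothesis' membership.
    """

    label: str
    kind: str  # "informative" | "complement" | "unconstrained"
    matrix: ConstraintMatrix | None = None

    def __post_init__(self):
        if self.kind not in ("informative", "complement", "unconstrained"):
            raise ValueError(f"unknown hypothesis kind: {self.kind!r}")
        if self.kind == "unconstrained" and self.matrix is not None:
            raise ValueError("unconstrained hypothesis carries no matrix")
        if self.kind != "unconstrained" and self.matrix is None:
            raise ValueError(f"{self.kind} hypothesis requires a matrix")


@dataclass(frozen=True)
class HypothesisSet:
    """An ordered set of M informative hypotheses sharing one layout."""

    hypotheses: tuple[Hypothesis, ...]
    layout: ConditionLayout

    def __init__(self, hypotheses: Iterable[Hypothesis], layout: ConditionLayout):
        hyps = tuple(hypotheses)
        if len(hyps) < 1:
            raise ValueError("a hypothesis set needs at least one hypothesis")
        labels = [h.label for h in hyps]
        if len(set(labels)) != len(labels):
            raise ValueError("hypothesis labels must be unique")
        for h in hyps:
            if h.kind != "informative":
                raise ValueError("hypothesis sets hold informative hypotheses only")
            if h.matrix.n_conditions != layout.n_conditions:
                raise ValueError(
                    f"hypothesis {h.label!r} has {h.matrix.n_conditions} columns, "
                    f"layout has {layout.n_conditions} conditions"
                )
        object.__setattr__(self, "hypotheses", hyps)
        object.__setattr__(self, "layout", layout)

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.hypotheses]

    def __len__(self) -> int:
        return len(self.hypotheses)

    def __getitem__(self, label: str) -> Hypothesis:
        for h in self.hypotheses:
            if h.label == label:
                return h
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Constraint mini-language parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+(?:\.\d+)?|\.\d+)|(?P<name>[A-Za-z_][A-Za-z0-9_.]*)"
    r"|(?P<op>[-+*/()><;,]))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens = []
    text = text.strip()
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            bad = text[pos:].strip().split()[0] if text[pos:].strip() else text[pos]
            raise HypothesisParseError(f"unrecognized token: {bad!r}")
        if m.lastgroup == "num":
            tokens.append(("num", m.group("num")))
        elif m.lastgroup == "name":
            tokens.append(("name", m.group("name")))
        else:
            tokens.append(("op", m.group("op")))
        pos = m.end()
    return tokens


class _ExprParser:
    """Recursive-descent parser for one side of an inequality.

    Produces a coefficient vector over the layout's conditions.  Bare numeric
    constants are rejected except as divisors/multipliers, because constraint
    rows compare linear combinations of probabilities (no offsets).
    """

    def __init__(self, tokens: list[tuple[str, str]], layout: ConditionLayout):
        self.tokens = tokens
        self.pos = 0
        self.layout = layout

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse_expression(self) -> np.ndarray:
        sign = 1.0
        kind, val = self.peek()
        if (kind, val) == ("op", "-"):
            self.take()
            sign = -1.0
        coef = sign * self.parse_term()
        while True:
            kind, val = self.peek()
            if (kind, val) == ("op", "+"):
                self.take()
                coef = coef + self.parse_term()
            elif (kind, val) == ("op", "-"):
                self.take()
                coef = coef - self.parse_term()
            else:
                return coef

    def parse_term(self) -> np.ndarray:
        coef = self.parse_atom()
        while True:
            kind, val = self.peek()
            if (kind, val) == ("op", "/"):
                self.take()
                nk, nv = self.take()
                if nk != "num":
                    raise HypothesisParseError(
                        f"expected a numeric divisor, got {nv!r}"
                    )
                divisor = float(nv)
                if divisor == 0:
                    raise HypothesisParseError("division by zero in constraint")
                coef = coef / divisor
            elif (kind, val) == ("op", "*"):
                self.take()
                nk, nv = self.take()
                if nk != "num":
                    raise HypothesisParseError(
                        f"expected a numeric multiplier, got {nv!r}"
                    )
                coef = coef * float(nv)
            else:
                return coef

    def parse_atom(self) -> np.ndarray:
        kind, val = self.take()
        if kind == "name":
            vec = np.zeros(self.layout.n_conditions)
            try:
                vec[self.layout.index(val)] = 1.0
            except KeyError:
                raise HypothesisParseError(f"unknown condition name: {val!r}") from None
            return vec
        if kind == "num":
            nk, nv = self.peek()
            if (nk, nv) == ("op", "*"):
                self.take()
                return float(val) * self.parse_atom()
            raise HypothesisParseError(
                f"bare constant {val!r} is not a valid constraint term"
            )
        if (kind, val) == ("op", "("):
            inner = self.parse_expression()
            ck, cv = self.take()
            if (ck, cv) != ("op", ")"):
                raise HypothesisParseError("unbalanced parentheses in constraint")
            return inner
        raise HypothesisParseError(f"unexpected token {val!r} in constraint")


def _split_toplevel(tokens: list[tuple[str, str]], sep: str) -> list[list[tuple[str, str]]]:
    groups, depth, current = [], 0, []
    for tok in tokens:
        kind, val = tok
        if kind == "op" and val == "(":
            depth += 1
        elif kind == "op" and val == ")":
            depth -= 1
        if kind == "op" and val == sep and depth == 0:
            groups.append(current)
            current = []
        else:
            current.append(tok)
    groups.append(current)
    return groups


def parse_hypothesis(text: str, layout: ConditionLayout, label: str = "H") -> Hypothesis:
    """Parse a constraint string into an informative :class:`Hypothesis`.

    Chains such as ``a > b > c`` expand into adjacent pairwise rows
    (``a > b`` and ``b > c``); implied constraints (``a > c``) are not added.
    ``;`` separates independent constraint groups, ``,`` between terms imposes
    no constraint, and a chain must not mix ``>`` and ``<``.
    """
    tokens = _tokenize(text)
    if not tokens:
        raise HypothesisParseError("empty constraint string")
    rows: list[np.ndarray] = []
    for group in _split_toplevel(tokens, ";"):
        for chain in _split_toplevel(group, ","):
            if not chain:
                raise HypothesisParseError("empty constraint chain")
            rows.extend(_parse_chain(chain, layout))
    if not rows:
        raise HypothesisParseError(
            "constraint string imposes no inequality (no '>' or '<' found)"
        )
    return Hypothesis(label=label, kind="informative", matrix=ConstraintMatrix(np.array(rows)))


def _parse_chain(tokens: list[tuple[str, str]], layout: ConditionLayout) -> list[np.ndarray]:
    # split on top-level comparison operators, remembering their directions
    sides: list[list[tuple[str, str]]] = []
    ops: list[str] = []
    depth, current = 0, []
    for tok in tokens:
        kind, val = tok
        if kind == "op" and val == "(":
            depth += 1
        elif kind == "op" and val == ")":
            depth -= 1
        if kind == "op" and val in (">", "<") and depth == 0:
            sides.append(current)
            ops.append(val)
            current = []
        else:
            current.append(tok)
    sides.append(current)

    if not ops:
        # a bare term list imposes no constraint; still validate the names
        for side in sides:
            parser = _ExprParser(side, layout)
            parser.parse_expression()
            if parser.pos != len(side):
                k, v = parser.peek()
                raise HypothesisParseError(f"unexpected token {v!r} in constraint")
        return []
    if len(set(ops)) > 1:
        raise HypothesisParseError(
            "mixed-direction chain ('>' and '<' in one chain); "
            "split it into ';'-separated groups"
        )
    exprs = []
    for side in sides:
        if not side:
            raise HypothesisParseError("comparison with an empty side")
        parser = _ExprParser(side, layout)
        exprs.append(parser.parse_expression())
        if parser.pos != len(side):
            k, v = parser.peek()
            raise HypothesisParseError(f"unexpected token {v!r} in constraint")
    rows = []
    for left, right in zip(exprs[:-1], exprs[1:]):
        row = left - right if ops[0] == ">" else right - left
        if np.all(row == 0):
            raise HypothesisParseError("constraint row reduces to 0 > 0")
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def complement_of(h: Hypothesis) -> Hypothesis:
    """The complement hypothesis: ``H_m`` is not true (some row violated)."""
    if h.kind != "informative":
        raise ValueError("complement is defined for informative hypotheses only")
    return Hypothesis(label=f"not {h.label}", kind="complement", matrix=h.matrix)


def membership(h: Hypothesis, pi: np.ndarray) -> np.ndarray:
    """Vectorized membership test of probability vectors in a hypothesis region.

    ``pi`` has shape (J,) or (N, J); returns a bool (scalar or length N).
    Rows are strict: a draw with any row product exactly zero lies on the
    boundary and satisfies neither the informative hypothesis nor its
    complement (a probability-zero event under continuous Beta draws).
    """
    pi = np.asarray(pi, dtype=float)
    single = pi.ndim == 1
    pi2 = np.atleast_2d(pi)
    if h.kind == "unconstrained":
        out = np.ones(pi2.shape[0], dtype=bool)
    else:
        prods = pi2 @ h.matrix.coefficients.T
        if h.kind == "informative":
            out = np.all(prods > 0, axis=1)
        else:
            # complement: some row strictly violated and none on the boundary
            out = np.any(prods < 0, axis=1) & ~np.any(prods == 0, axis=1)
    return out[0] if single else out


@dataclass(frozen=True)
class ConstraintDiagnostics:
    """Reporting-only summary of a constraint matrix."""

    n_rows: int
    n_conditions: int
    proportional_row_pairs: tuple[tuple[int, int], ...] = ()
    zero_rows: tuple[int, ...] = ()

    @property
    def warnings(self) -> list[str]:
        msgs = []
        for i, j in self.proportional_row_pairs:
            msgs.append(f"rows {i} and {j} are proportional (redundant constraint)")
        for i in self.zero_rows:
            msgs.append(f"row {i} is all zero (invariant violation)")
        return msgs


def validate_constraints(matrix) -> ConstraintDiagnostics:
    """Diagnose a constraint matrix: duplicate/proportional rows, zero rows."""
    coef = matrix.coefficients if isinstance(matrix, ConstraintMatrix) else (
        np.atleast_2d(np.asarray(matrix, dtype=float))
    )
    k = coef.shape[0]
    zero_rows = tuple(int(i) for i in np.where(np.all(coef == 0.0, axis=1))[0])
    prop = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = coef[i], coef[j]
            if np.all(a == 0) or np.all(b == 0):
                continue
            # proportional iff the 2 x J stack has rank 1
            if np.linalg.matrix_rank(np.vstack([a, b])) == 1:
                prop.append((i, j))
    return ConstraintDiagnostics(
        n_rows=k,
        n_conditions=coef.shape[1],
        proportional_row_pairs=tuple(prop),
        zero_rows=zero_rows,
    )


def full_ordering_permutation(h: Hypothesis) -> tuple[int, ...] | None:
    """If ``h`` is a complete simple ordering of all J conditions, return it.

    A complete simple ordering has K = J - 1 rows, each with exactly one +1
    and one -1 coefficient, chaining all conditions ``o_1 > o_2 > ... > o_J``.
    Returns the condition indices in decreasing order, or None.  For such
    hypotheses the prior complexity is exactly ``1/J!`` by exchangeability of
    the uniform prior.
    """
    if h.kind != "informative":
        return None
    coef = h.matrix.coefficients
    k, j = coef.shape
    if k != j - 1:
        return None
    successor: dict[int, int] = {}
    for row in coef:
        pos = np.where(row == 1.0)[0]
        neg = np.where(row == -1.0)[0]
        if len(pos) != 1 or len(neg) != 1 or np.count_nonzero(row) != 2:
            return None
        a, b = int(pos[0]), int(neg[0])
        if a in successor:
            return None
        successor[a] = b
    starts = set(successor) - set(successor.values())
    if len(starts) != 1:
        return None
    order = [starts.pop()]
    while order[-1] in successor:
        order.append(successor[order[-1]])
    if len(order) != j or len(set(order)) != j:
        return None
    return tuple(order)


def full_ordering_complexity(h: Hypothesis) -> float | None:
    """Exact prior complexity 1/J! for a complete simple ordering, else None."""
    perm = full_ordering_permutation(h)
    if perm is None:
        return None
    return 1.0 / math.factorial(len(perm))
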