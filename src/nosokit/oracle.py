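"""Independent brute-force oracles for every computed quantity.

These deliberately share no machinery with the production modules: the
evaluator walks the expression tree over plain Python sets, enumeration uses
``itertools.combinations`` over the whole universe, minimality re-tests every
proper subset, and MPCS is a literal double loop with ``math.sqrt``.  They
are exponential and intended for small universes (n <= 16) in tests; the
production path is checked against them, never the other way around.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations
from math import sqrt
from typing import Iterable

from .criteria import And, AtLeast, DisorderDefinition, Expression, Or, Var
from .enumeration import CSSCSet

__all__ = ["OracleResult", "brute_force_oracle", "naive_mpcs", "NaiveMPCS"]

_MAX_N = 16


def _satisfies(expr: Expression, present: frozenset[str]) -> bool:
    """Literal restatement of the criteria semantics (no compilation)."""
    if isinstance(expr, Var):
        return expr.symptom in present
    if isinstance(expr, And):
        return all(_satisfies(c, present) for c in expr.children)
    if isinstance(expr, Or):
        return any(_satisfies(c, present) for c in expr.children)
    if isinstance(expr, AtLeast):
        return sum(_satisfies(c, present) for c in expr.children) >= expr.k
    raise TypeError(type(expr).__name__)


def _powerset(items: Iterable[str]):
    items = list(items)
    return chain.from_iterable(
        combinations(items, r) for r in range(len(items) + 1)
    )


@dataclass(frozen=True)
class OracleResult:
    extension: frozenset[frozenset[str]]  # all satisfying subsets of the universe
    irredundant: frozenset[frozenset[str]]
    relevant: frozenset[str]
    weakly_irredundant: frozenset[frozenset[str]]


def brute_force_oracle(defn: DisorderDefinition) -> OracleResult:
    """Compute extension, minimal sets, relevance and the weakly irredundant
    set by exhaustive iteration over all subsets of the universe."""
    n = len(defn.universe)
    if n > _MAX_N:
        raise ValueError(f"oracle limited to {_MAX_N} symptoms, got {n}")
    extension = frozenset(
        frozenset(c)
        for c in _powerset(defn.universe.symptoms)
        if _satisfies(defn.expression, frozenset(c))
    )
    irredundant = frozenset(
        c
        for c in extension
        if not any(
            frozenset(sub) in extension
            for sub in _powerset(c)
            if frozenset(sub) != c
        )
    )
    relevant = frozenset().union(*irredundant) if irredundant else frozenset()
    weakly = frozenset(c for c in extension if c <= relevant)
    return OracleResult(extension, irredundant, relevant, weakly)


@dataclass(frozen=True)
class NaiveMPCS:
    mpcs_max: float
    mpcs_mean: float


def naive_mpcs(a: CSSCSet, b: CSSCSet) -> NaiveMPCS:
    """Reference MPCS: plain double loop over set-encoded CSSC columns."""
    def best_matches(frm: CSSCSet, to: CSSCSet) -> list[float]:
        out = []
        for c in frm.combinations:
            best = 0.0
            for d in to.combinations:
                cos = len(c & d) / sqrt(len(c) * len(d))
                if cos > best:
                    best = cos
            out.append(best)
        return out

    ab = best_matches(a, b)
    ba = best_matches(b, a)
    return NaiveMPCS(
        mpcs_max=max(max(ab), max(ba)),
        mpcs_mean=max(sum(ab) / len(ab), sum(ba) / len(ba)),
    )
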