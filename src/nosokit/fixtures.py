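"""Packaged fixtures: the four-disorder toy system and a DSM-like example.

The toy system lives on the universe {a, b, c, d}:

* W — symptom a and at least one of b or c; weakly irredundant CSSCs
  {ab, ac, abc}.
* X — symptom d and at least one of b or c; weakly irredundant CSSCs
  {bd, cd, bcd}.
* Y — symptom b and at least one of c or d (reconstructed from its reference
  CSSC set); weakly irredundant CSSCs {bc, bd, bcd}.
* Z — at least one of a or d; minimal CSSCs {a} and {d}.

The reference illustration lists Z's weakly irredundant CSSCs as the two
singletons {a} and {d}; under the formal definition the union {a, d} is
weakly irredundant as well (upward closure over the relevant universe).
:func:`toy_disorders` returns full definitions (enumeration yields all
three); :func:`toy_cssc_sets` returns the literal reference sets (Z as the
two singletons), which reproduce the reference similarity table either way.

The "MDD-like" definition — at least five of nine symptoms, at least one of
which must come from the two core symptoms — exercises the DSM-style
cardinality pattern at realistic scale (227 weakly irredundant CSSCs); it is
a simplified stand-in, not a transcription of any manual's criteria.

A small synthetic harmonization table and random monotone definition
generator support the property-test suites.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .criteria import (
    And,
    AtLeast,
    DisorderDefinition,
    Expression,
    Or,
    SymptomUniverse,
    Var,
    parse_criteria_file,
)
from .enumeration import CSSCSet, enumerate_weakly_irredundant

__all__ = [
    "toy_universe",
    "toy_disorders",
    "toy_cssc_sets",
    "mdd_like_definition",
    "data_path",
    "RandomCriteriaSpec",
    "random_definition",
]


def data_path(name: str) -> Path:
    """Path to a packaged data file (criteria fixtures, schema, tables)."""
    return Path(resources.files("nosokit.data") / name)


def toy_universe() -> SymptomUniverse:
    return SymptomUniverse(("a", "b", "c", "d"))


def toy_disorders() -> list[DisorderDefinition]:
    """The four toy disorders W, X, Y, Z as full definitions."""
    return parse_criteria_file(data_path("toy_disorders.json"))


def toy_cssc_sets() -> dict[str, CSSCSet]:
    """The reference toy CSSC sets, keyed by disorder name.

    W, X and Y are produced by enumeration from their definitions; Z is the
    literal reference set {a}, {d} (see module docstring).
    """
    defs = {d.name: d for d in toy_disorders()}
    out = {
        name: enumerate_weakly_irredundant(defs[name]) for name in ("W", "X", "Y")
    }
    out["Z"] = CSSCSet.from_combinations(
        "Z", toy_universe(), [{"a"}, {"d"}], relevant=frozenset({"a", "d"})
    )
    return out


def mdd_like_definition() -> DisorderDefinition:
    """At least five of nine symptoms, including at least one of two core ones."""
    return parse_criteria_file(data_path("mdd_like.json"))[0]


# ---------------------------------------------------------------------------
# Random monotone definitions for property tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomCriteriaSpec:
    """Shape parameters for random monotone criteria generation.

    ``n`` is the universe size; each definition is a conjunction of
    ``n_clauses`` clauses, each clause a VAR, an OR over symptoms, or an
    AT_LEAST(k >= 1) over symptoms.  Every clause requires at least one
    symptom, so generated definitions are never satisfied by the empty set.
    """

    n: int = 10
    n_clauses: int = 3
    max_group: int = 6
    seed: int = 0


def random_definition(spec: RandomCriteriaSpec) -> DisorderDefinition:
    """A reproducible random monotone definition (valid by construction)."""
    if spec.n < 1 or spec.n_clauses < 1:
        raise ValueError("need n >= 1 and n_clauses >= 1")
    rng = random.Random(spec.seed)
    symptoms = tuple(f"s{i + 1}" for i in range(spec.n))
    universe = SymptomUniverse(symptoms)
    clauses: list[Expression] = []
    for _ in range(spec.n_clauses):
        size = rng.randint(1, min(spec.max_group, spec.n))
        group = rng.sample(symptoms, size)
        kind = rng.choice(("var", "or", "at_least")) if size > 1 else "var"
        if kind == "var":
            clauses.append(Var(group[0]))
        elif kind == "or":
            clauses.append(Or(tuple(Var(s) for s in group)))
        else:
            k = rng.randint(1, size)
            clauses.append(AtLeast(k, tuple(Var(s) for s in group)))
    expr: Expression = clauses[0] if len(clauses) == 1 else And(tuple(clauses))
    return DisorderDefinition(
        f"random-{spec.seed}", universe, expr, {"generator": "random_definition"}
    )
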