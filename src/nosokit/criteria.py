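"""Machine-actionable diagnostic criteria: symptom universes, monotone
criteria expressions, disorder definitions, and their evaluation.

A disorder definition is an *intensional* description: a logical rule over a
fixed set of symptoms that decides which symptom subsets qualify as
criteria-satisfying symptom combinations (CSSCs).  The expression language is
deliberately restricted to monotone constructs — VAR, AND, OR and the
cardinality constraint AT_LEAST(k, ...) — because narrative diagnostic manuals
phrase inclusion criteria as "symptom a and at least one of b or c" or
"five (or more) of the following nine".  Monotonicity (adding symptoms never
falsifies a satisfied rule) is what makes exhaustive enumeration, minimality
and subsumption analysis well defined.

Exclusion ("not better explained by ...") and weighted criteria are out of
scope by design.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

__all__ = [
    "CriteriaError",
    "ParseError",
    "ValidationError",
    "canonical_term",
    "SymptomUniverse",
    "Expression",
    "Var",
    "And",
    "Or",
    "AtLeast",
    "SymptomCombination",
    "DisorderDefinition",
    "evaluate",
    "parse_criteria",
    "parse_criteria_file",
    "serialize_criteria",
    "write_criteria_file",
    "load_harmonization_table",
    "normalize_terms",
]


class CriteriaError(ValueError):
    """Base class for criteria-model errors."""


class ParseError(CriteriaError):
    """Raised when a criteria file is structurally malformed."""


class ValidationError(CriteriaError):
    """Raised when a parsed definition violates a model invariant."""


def canonical_term(term: str) -> str:
    """Canonicalize a symptom identifier or free-text term.

    Trims surrounding whitespace, collapses internal runs of whitespace to a
    single space, and case-folds.  All symptom-id comparisons in the package
    go through this normalization.
    """
    return " ".join(term.split()).casefold()


# ---------------------------------------------------------------------------
# Symptom universe
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymptomUniverse:
    """An ordered set of unique symptom identifiers.

    The order is total and deterministic: the explicit order in which the ids
    were supplied (typically file order), or lexicographic if constructed via
    :meth:`from_ids` with ``sort=True``.  The order fixes bit positions for
    combination bitsets and row order for CSSC matrices.
    """

    symptoms: tuple[str, ...]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canon = tuple(canonical_term(s) for s in self.symptoms)
        if any(not s for s in canon):
            raise ValidationError("empty symptom identifier in universe")
        if len(set(canon)) != len(canon):
            dupes = sorted({s for s in canon if canon.count(s) > 1})
            raise ValidationError(f"duplicate symptom identifiers: {dupes}")
        object.__setattr__(self, "symptoms", canon)
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(canon)})

    @classmethod
    def from_ids(cls, ids: Iterable[str], *, sort: bool = False,
                 labels: Mapping[str, str] | None = None) -> "SymptomUniverse":
        ids = [canonical_term(s) for s in ids]
        if sort:
            ids = sorted(set(ids))
        return cls(tuple(ids), labels or {})

    def index(self, symptom: str) -> int:
        try:
            return self._index[canonical_term(symptom)]  # type: ignore[attr-defined]
        except KeyError:
            raise ValidationError(f"symptom {symptom!r} not in universe") from None

    def __contains__(self, symptom: object) -> bool:
        return isinstance(symptom, str) and canonical_term(symptom) in self._index  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.symptoms)

    def __iter__(self):
        return iter(self.symptoms)


# ---------------------------------------------------------------------------
# Criteria expressions (monotone by construction)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Var:
    symptom: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "symptom", canonical_term(self.symptom))

    def support(self) -> frozenset[str]:
        return frozenset({self.symptom})

    def satisfied_by(self, present: frozenset[str]) -> bool:
        return self.symptom in present

    def to_json(self) -> dict:
        return {"var": self.symptom}


@dataclass(frozen=True)
class And:
    children: tuple["Expression", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if not self.children:
            raise ValidationError("AND requires at least one child")

    def support(self) -> frozenset[str]:
        return frozenset().union(*(c.support() for c in self.children))

    def satisfied_by(self, present: frozenset[str]) -> bool:
        return all(c.satisfied_by(present) for c in self.children)

    def to_json(self) -> dict:
        return {"and": [c.to_json() for c in self.children]}


@dataclass(frozen=True)
class Or:
    children: tuple["Expression", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if not self.children:
            raise ValidationError("OR requires at least one child")

    def support(self) -> frozenset[str]:
        return frozenset().union(*(c.support() for c in self.children))

    def satisfied_by(self, present: frozenset[str]) -> bool:
        return any(c.satisfied_by(present) for c in self.children)

    def to_json(self) -> dict:
        return {"or": [c.to_json() for c in self.children]}


@dataclass(frozen=True)
class AtLeast:
    """Cardinality constraint: at least ``k`` of the children are satisfied."""

    k: int
    children: tuple["Expression", ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "children", tuple(self.children))
        if not isinstance(self.k, int) or self.k < 0:
            raise ValidationError("AT_LEAST threshold must be a non-negative integer")
        if self.k > len(self.children):
            raise ValidationError(
                f"AT_LEAST threshold {self.k} exceeds number of children "
                f"({len(self.children)})"
            )

    def support(self) -> frozenset[str]:
        if not self.children:
            return frozenset()
        return frozenset().union(*(c.support() for c in self.children))

    def satisfied_by(self, present: frozenset[str]) -> bool:
        need = self.k
        if need == 0:
            return True
        for c in self.children:
            if c.satisfied_by(present):
                need -= 1
                if need == 0:
                    return True
        return False

    def to_json(self) -> dict:
        return {"at_least": self.k, "of": [c.to_json() for c in self.children]}


Expression = Union[Var, And, Or, AtLeast]


def expression_from_json(node: object, *, where: str = "expression") -> Expression:
    """Build an :class:`Expression` from the criteria JSON dialect."""
    if not isinstance(node, dict):
        raise ParseError(f"{where}: expected an object, got {type(node).__name__}")
    keys = set(node)
    if keys == {"var"}:
        if not isinstance(node["var"], str) or not node["var"].strip():
            raise ParseError(f"{where}: 'var' must be a non-empty string")
        return Var(node["var"])
    if keys == {"and"}:
        return And(tuple(
            expression_from_json(c, where=f"{where}.and[{i}]")
            for i, c in enumerate(_child_list(node["and"], where, "and"))
        ))
    if keys == {"or"}:
        return Or(tuple(
            expression_from_json(c, where=f"{where}.or[{i}]")
            for i, c in enumerate(_child_list(node["or"], where, "or"))
        ))
    if keys == {"at_least", "of"}:
        k = node["at_least"]
        if not isinstance(k, int) or isinstance(k, bool):
            raise ParseError(f"{where}: 'at_least' must be an integer")
        children = tuple(
            expression_from_json(c, where=f"{where}.of[{i}]")
            for i, c in enumerate(_child_list(node["of"], where, "of"))
        )
        try:
            return AtLeast(k, children)
        except ValidationError as exc:
            raise ParseError(f"{where}: {exc}") from None
    raise ParseError(
        f"{where}: unrecognized node keys {sorted(keys)}; expected one of "
        "{'var'}, {'and'}, {'or'}, {'at_least','of'}"
    )


def _child_list(obj: object, where: str, key: str) -> list:
    if not isinstance(obj, list) or not obj:
        raise ParseError(f"{where}: '{key}' must be a non-empty list")
    return obj


# ---------------------------------------------------------------------------
# Symptom combinations and disorder definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SymptomCombination:
    """A subset of a symptom universe (the extensional object of the model).

    Rendering is ternary relative to a disorder: 1 for present relevant
    symptoms, 0 for absent relevant symptoms, and "?" for symptoms that are
    diagnostically irrelevant for the disorder under consideration.
    """

    present: frozenset[str]
    universe: SymptomUniverse

    def __post_init__(self) -> None:
        present = frozenset(canonical_term(s) for s in self.present)
        outside = present - frozenset(self.universe.symptoms)
        if outside:
            raise ValidationError(
                f"symptoms outside universe: {sorted(outside)}"
            )
        object.__setattr__(self, "present", present)

    def ternary(self, relevant: frozenset[str] | None = None) -> tuple[str, ...]:
        """Render over the universe order as '1'/'0'/'?' strings."""
        rel = relevant if relevant is not None else frozenset(self.universe.symptoms)
        out = []
        for s in self.universe:
            if s not in rel:
                out.append("?")
            else:
                out.append("1" if s in self.present else "0")
        return tuple(out)

    def __len__(self) -> int:
        return len(self.present)

    def __le__(self, other: "SymptomCombination") -> bool:
        return self.present <= other.present

    def __lt__(self, other: "SymptomCombination") -> bool:
        return self.present < other.present


@dataclass(frozen=True)
class DisorderDefinition:
    """A named monotone criteria expression over a symptom universe."""

    name: str
    universe: SymptomUniverse
    expression: Expression
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise ValidationError("disorder name must be non-empty")
        unknown = self.expression.support() - frozenset(self.universe.symptoms)
        if unknown:
            raise ValidationError(
                f"disorder {self.name!r}: expression references symptoms "
                f"outside the universe: {sorted(unknown)}"
            )
        # The empty combination must not satisfy the criteria: a zero vector
        # has no direction, so cosine similarity would be undefined, and a
        # trivially satisfiable definition has an empty irredundant structure.
        if self.expression.satisfied_by(frozenset()):
            raise ValidationError(
                f"disorder {self.name!r}: expression is satisfied by the "
                "empty symptom set (trivially satisfiable definitions are "
                "rejected)"
            )

    def support(self) -> frozenset[str]:
        return self.expression.support()


def evaluate(defn: DisorderDefinition, combo: SymptomCombination | Iterable[str]) -> bool:
    """Decide whether a symptom combination satisfies a disorder's criteria.

    ``combo`` may be a :class:`SymptomCombination` or any iterable of symptom
    ids; ids must belong to the definition's universe.
    """
    if isinstance(combo, SymptomCombination):
        present = combo.present
    else:
        present = frozenset(canonical_term(s) for s in combo)
    outside = present - frozenset(defn.universe.symptoms)
    if outside:
        raise ValidationError(
            f"symptoms outside the universe of {defn.name!r}: {sorted(outside)}"
        )
    return defn.expression.satisfied_by(present)


# ---------------------------------------------------------------------------
# Criteria file dialect (UTF-8 JSON)
# ---------------------------------------------------------------------------
#
#   {"universe": ["a", "b", ...],
#    "disorders": [{"name": "W",
#                   "expression": {"and": [{"var": "a"},
#                                          {"at_least": 1,
#                                           "of": [{"var": "b"}, {"var": "c"}]}]},
#                   "metadata": {...}}, ...]}
#
# The universe order in the file is authoritative; if "universe" is omitted,
# the union of expression supports is used in lexicographic order.


def parse_criteria(obj: object, *, source: str = "<criteria>") -> list[DisorderDefinition]:
    if not isinstance(obj, dict):
        raise ParseError(f"{source}: top level must be a JSON object")
    disorders = obj.get("disorders")
    if not isinstance(disorders, list) or not disorders:
        raise ParseError(f"{source}: 'disorders' must be a non-empty list")

    universe_ids = obj.get("universe")
    labels = obj.get("labels", {})
    if labels and not isinstance(labels, dict):
        raise ParseError(f"{source}: 'labels' must be an object")

    parsed: list[tuple[str, Expression, dict]] = []
    for i, d in enumerate(disorders):
        if not isinstance(d, dict) or "name" not in d or "expression" not in d:
            raise ParseError(
                f"{source}: disorders[{i}] must be an object with "
                "'name' and 'expression'"
            )
        name = d["name"]
        if not isinstance(name, str) or not name.strip():
            raise ParseError(f"{source}: disorders[{i}].name must be a non-empty string")
        expr = expression_from_json(
            d["expression"], where=f"disorder {name!r} expression"
        )
        meta = d.get("metadata", {})
        if not isinstance(meta, dict):
            raise ParseError(f"{source}: disorder {name!r}: metadata must be an object")
        parsed.append((name, expr, meta))

    names = [n for n, _, _ in parsed]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ParseError(f"{source}: duplicate disorder names: {dupes}")

    if universe_ids is not None:
        if not isinstance(universe_ids, list) or not all(
            isinstance(s, str) for s in universe_ids
        ):
            raise ParseError(f"{source}: 'universe' must be a list of strings")
        universe = SymptomUniverse(tuple(universe_ids), labels)
    else:
        union: set[str] = set()
        for _, expr, _ in parsed:
            union |= expr.support()
        universe = SymptomUniverse.from_ids(sorted(union), labels=labels)

    out = []
    for name, expr, meta in parsed:
        try:
            out.append(DisorderDefinition(name, universe, expr, meta))
        except ValidationError as exc:
            raise ValidationError(f"{source}: {exc}") from None
    return out


def parse_criteria_file(path: str | Path) -> list[DisorderDefinition]:
    """Parse a criteria JSON file into validated disorder definitions."""
    path = Path(path)
    try:
        obj = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from None
    return parse_criteria(obj, source=str(path))


def serialize_criteria(defns: Sequence[DisorderDefinition]) -> dict:
    """Serialize definitions back to the criteria JSON dialect.

    All definitions must share one universe; round-trips with
    :func:`parse_criteria`.
    """
    if not defns:
        raise ValidationError("nothing to serialize")
    universe = defns[0].universe
    if any(d.universe.symptoms != universe.symptoms for d in defns):
        raise ValidationError("definitions do not share a universe")
    doc: dict = {"universe": list(universe.symptoms)}
    if universe.labels:
        doc["labels"] = dict(universe.labels)
    doc["disorders"] = [
        {"name": d.name, "expression": d.expression.to_json(),
         **({"metadata": dict(d.metadata)} if d.metadata else {})}
        for d in defns
    ]
    return doc


def write_criteria_file(defns: Sequence[DisorderDefinition], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(serialize_criteria(defns), indent=2) + "\n", encoding="utf-8"
    )


# ---------------------------------------------------------------------------
# Symptom harmonization
# ---------------------------------------------------------------------------


def load_harmonization_table(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV mapping source terms to canonical symptom ids.

    Expected header: ``source<TAB>canonical``.  Both columns are canonicalized
    (trim, whitespace-collapse, case-fold) on load.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise ParseError(f"{path}: empty harmonization table")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if header[:2] != ["source", "canonical"]:
        raise ParseError(
            f"{path}: expected header 'source\\tcanonical', got {lines[0]!r}"
        )
    mapping: dict[str, str] = {}
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}:{ln}: expected two tab-separated columns")
        src, dst = canonical_term(parts[0]), canonical_term(parts[1])
        if src in mapping and mapping[src] != dst:
            raise ParseError(f"{path}:{ln}: conflicting mapping for {src!r}")
        mapping[src] = dst
    return mapping


def normalize_terms(
    terms: Sequence[str],
    mapping: Mapping[str, str],
    *,
    on_unmapped: str = "error",
) -> list[str]:
    """Map free-text symptom terms onto the canonical vocabulary.

    Every term is canonicalized first, so inputs differing only in case or
    whitespace map identically.  A term absent from the mapping is either an
    error (``on_unmapped="error"``, listing all offenders) or passed through
    canonicalized (``on_unmapped="keep"``).  Terms already canonical map to
    themselves even without a table entry.
    """
    if on_unmapped not in ("error", "keep"):
        raise ValueError("on_unmapped must be 'error' or 'keep'")
    canon_map = {canonical_term(k): canonical_term(v) for k, v in mapping.items()}
    canonical_ids = set(canon_map.values())
    out: list[str] = []
    unmapped: list[str] = []
    for term in terms:
        key = canonical_term(term)
        if key in canon_map:
            out.append(canon_map[key])
        elif key in canonical_ids:
            out.append(key)
        else:
            unmapped.append(term)
            out.append(key)
    if unmapped and on_unmapped == "error":
        raise ValidationError(f"unmapped terms: {unmapped}")
    return out
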