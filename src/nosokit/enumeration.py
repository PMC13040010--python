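"""Enumeration and classification of criteria-satisfying symptom combinations.

For a disorder definition the *extension* is the set of all symptom subsets
satisfying the criteria.  Within it we distinguish:

* **irredundant** CSSCs — minimal satisfying sets (no proper subset satisfies);
* **relevant** symptoms — those appearing in at least one irredundant CSSC;
* **weakly irredundant** CSSCs — satisfying sets containing only relevant
  symptoms (the upward closure of the irredundant sets inside the relevant
  universe);
* **strongly redundant** CSSCs — satisfying sets containing at least one
  irrelevant symptom.

Only the weakly irredundant set is finite-and-small in interesting cases and
it is the object all downstream analyses (delineation, similarity,
projection) operate on.

Combinations are manipulated as integer bitsets keyed to the universe's
deterministic symptom order, which makes subset tests and column ordering
exact and cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

from .criteria import (
    And,
    AtLeast,
    CriteriaError,
    DisorderDefinition,
    Expression,
    Or,
    SymptomCombination,
    SymptomUniverse,
    Var,
    evaluate,
)

__all__ = [
    "EnumerationCapError",
    "CSSCSet",
    "CSSCMatrix",
    "enumerate_weakly_irredundant",
    "irredundant_csscs",
    "relevant_symptoms",
    "classify",
    "count_weakly_irredundant",
    "to_matrix",
    "DEFAULT_CAP",
]

DEFAULT_CAP = 24  # enumeration over 2^cap subsets of the expression support


class EnumerationCapError(CriteriaError):
    """Support exceeds the enumeration cap; use count-only / combinatorial mode."""


# ---------------------------------------------------------------------------
# Bit-level machinery
# ---------------------------------------------------------------------------


def _compile(expr: Expression, bit_of: Mapping[str, int]) -> Callable[[int], bool]:
    """Compile an expression into a predicate on bitmasks."""
    if isinstance(expr, Var):
        bit = 1 << bit_of[expr.symptom]
        return lambda m, _b=bit: bool(m & _b)
    children = [_compile(c, bit_of) for c in expr.children]
    if isinstance(expr, And):
        return lambda m, _c=children: all(f(m) for f in _c)
    if isinstance(expr, Or):
        return lambda m, _c=children: any(f(m) for f in _c)
    if isinstance(expr, AtLeast):
        k = expr.k
        if k == 0:
            return lambda m: True

        def at_least(m: int, _c=children, _k=k) -> bool:
            need = _k
            for f in _c:
                if f(m):
                    need -= 1
                    if need == 0:
                        return True
            return False

        return at_least
    raise TypeError(f"unknown expression node {type(expr).__name__}")


def _mask_to_set(mask: int, order: Sequence[str]) -> frozenset[str]:
    return frozenset(s for i, s in enumerate(order) if mask >> i & 1)


def _satisfying_masks(defn: DisorderDefinition, cap: int) -> tuple[list[int], list[str]]:
    """All satisfying subsets of the expression support, as bitmasks.

    Bit positions follow the universe order restricted to the support, so
    masks sort identically to full-universe bit patterns.
    """
    support = sorted(defn.support(), key=defn.universe.index)
    n = len(support)
    if n > cap:
        raise EnumerationCapError(
            f"disorder {defn.name!r}: expression support has {n} symptoms, "
            f"exceeding the enumeration cap of {cap}; use combinatorial "
            "counting or raise the cap"
        )
    bit_of = {s: i for i, s in enumerate(support)}
    sat = _compile(defn.expression, bit_of)
    # Monotone pruning is possible, but plain iteration in ascending mask
    # order is simple, deterministic and fast enough below the cap.
    masks = [m for m in range(1, 1 << n) if sat(m)]
    return masks, support


def _minimal_masks(masks: Sequence[int]) -> list[int]:
    """Antichain of minimal masks (no returned mask strictly contains another)."""
    minimal: list[int] = []
    for m in sorted(masks, key=lambda x: (bin(x).count("1"), x)):
        if not any(mm & m == mm for mm in minimal):
            minimal.append(m)
    minimal.sort()
    return minimal


# ---------------------------------------------------------------------------
# Public containers
# ---------------------------------------------------------------------------

IRREDUNDANT = "irredundant"
WEAKLY_IRREDUNDANT = "weakly_irredundant"
REDUNDANT = "redundant"
STRONGLY_REDUNDANT = "strongly_redundant"


@dataclass(frozen=True)
class CSSCSet:
    """A disorder's weakly irredundant CSSCs with classification flags.

    ``combinations`` are ordered by their bit pattern in the universe's
    symptom order (deterministic column order for matrices and reports).
    ``flags`` maps each combination to a subset of
    {"irredundant", "weakly_irredundant", "redundant"}.
    """

    name: str
    universe: SymptomUniverse
    combinations: tuple[frozenset[str], ...]
    relevant: frozenset[str]
    flags: Mapping[frozenset[str], frozenset[str]] = field(default_factory=dict)

    @property
    def irredundant(self) -> tuple[frozenset[str], ...]:
        return tuple(
            c for c in self.combinations if IRREDUNDANT in self.flags.get(c, ())
        )

    def __len__(self) -> int:
        return len(self.combinations)

    def __contains__(self, combo: object) -> bool:
        if isinstance(combo, SymptomCombination):
            combo = combo.present
        return combo in set(self.combinations)

    @classmethod
    def from_definition(cls, defn: DisorderDefinition, *, cap: int = DEFAULT_CAP) -> "CSSCSet":
        return enumerate_weakly_irredundant(defn, cap=cap)

    @classmethod
    def from_combinations(
        cls,
        name: str,
        universe: SymptomUniverse,
        combinations: Iterable[Iterable[str]],
        *,
        relevant: Iterable[str] | None = None,
    ) -> "CSSCSet":
        """Build a CSSC set from explicit combinations (e.g. reference sets).

        The relevant symptom set defaults to the union of the minimal
        combinations; flags are derived from subset structure alone.
        """
        combos = sorted(
            {frozenset(c) for c in combinations},
            key=lambda c: _set_key(c, universe),
        )
        if not combos:
            raise CriteriaError(f"{name!r}: empty CSSC set")
        for c in combos:
            outside = c - frozenset(universe.symptoms)
            if outside:
                raise CriteriaError(f"{name!r}: symptoms outside universe: {sorted(outside)}")
        minimal = [c for c in combos if not any(o < c for o in combos)]
        rel = (
            frozenset(relevant)
            if relevant is not None
            else frozenset().union(*minimal)
        )
        flags = {}
        for c in combos:
            f = {WEAKLY_IRREDUNDANT}
            if c in minimal:
                f.add(IRREDUNDANT)
            else:
                f.add(REDUNDANT)
            flags[c] = frozenset(f)
        return cls(name, universe, tuple(combos), rel, flags)


def _set_key(combo: frozenset[str], universe: SymptomUniverse) -> int:
    key = 0
    for s in combo:
        key |= 1 << universe.index(s)
    return key


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def enumerate_weakly_irredundant(
    defn: DisorderDefinition, *, cap: int = DEFAULT_CAP
) -> CSSCSet:
    """Enumerate the weakly irredundant CSSCs of a disorder.

    Returns exactly the satisfying subsets of the relevant symptom set, each
    flagged as irredundant or (weakly irredundant but) redundant.
    """
    masks, support = _satisfying_masks(defn, cap)
    minimal = _minimal_masks(masks)
    rel_mask = 0
    for m in minimal:
        rel_mask |= m
    weakly = [m for m in masks if m & ~rel_mask == 0]
    weakly.sort()
    minimal_set = set(minimal)

    combos = tuple(_mask_to_set(m, support) for m in weakly)
    relevant = _mask_to_set(rel_mask, support)
    flags = {}
    for m, c in zip(weakly, combos):
        f = {WEAKLY_IRREDUNDANT}
        f.add(IRREDUNDANT if m in minimal_set else REDUNDANT)
        flags[c] = frozenset(f)
    return CSSCSet(defn.name, defn.universe, combos, relevant, flags)


def irredundant_csscs(
    defn: DisorderDefinition, *, cap: int = DEFAULT_CAP
) -> tuple[frozenset[str], ...]:
    """The minimal satisfying symptom sets of a disorder."""
    masks, support = _satisfying_masks(defn, cap)
    return tuple(_mask_to_set(m, support) for m in _minimal_masks(masks))


def relevant_symptoms(
    defn: DisorderDefinition, *, cap: int = DEFAULT_CAP
) -> frozenset[str]:
    """Symptoms appearing in at least one irredundant CSSC."""
    minimal = irredundant_csscs(defn, cap=cap)
    return frozenset().union(*minimal) if minimal else frozenset()


def classify(
    defn: DisorderDefinition,
    combo: SymptomCombination | Iterable[str],
    *,
    cap: int = DEFAULT_CAP,
) -> frozenset[str]:
    """Classify a satisfying combination.

    Returns a flag set drawn from {"irredundant", "weakly_irredundant",
    "redundant", "strongly_redundant"}.  A combination that does not satisfy
    the criteria is not a CSSC and raises an error.
    """
    present = (
        combo.present
        if isinstance(combo, SymptomCombination)
        else frozenset(combo)
    )
    if not evaluate(defn, present):
        raise CriteriaError(
            f"{sorted(present)} does not satisfy {defn.name!r}: not a CSSC"
        )
    rel = relevant_symptoms(defn, cap=cap)
    flags: set[str] = set()
    if present <= rel:
        flags.add(WEAKLY_IRREDUNDANT)
        minimal = not any(
            evaluate(defn, present - {s}) for s in present
        )
        flags.add(IRREDUNDANT if minimal else REDUNDANT)
    else:
        flags.add(STRONGLY_REDUNDANT)
        flags.add(REDUNDANT)
    return frozenset(flags)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


class _NotCombinatorial(Exception):
    pass


def _atleast_clauses(expr: Expression) -> list[tuple[int, frozenset[str]]]:
    """Flatten a conjunction of cardinality clauses over plain symptoms.

    Accepted shapes: AND of clauses, or a single clause, where a clause is
    VAR(s) (== at least 1 of {s}), OR of VARs (== at least 1), or
    AT_LEAST(k, VARs).  Anything else is not in the combinatorial fragment.
    """
    top = list(expr.children) if isinstance(expr, And) else [expr]
    clauses: list[tuple[int, frozenset[str]]] = []
    for node in top:
        if isinstance(node, Var):
            clauses.append((1, frozenset({node.symptom})))
        elif isinstance(node, Or):
            if not all(isinstance(c, Var) for c in node.children):
                raise _NotCombinatorial
            clauses.append((1, frozenset(c.symptom for c in node.children)))
        elif isinstance(node, AtLeast):
            if not all(isinstance(c, Var) for c in node.children):
                raise _NotCombinatorial
            if node.k == 0:
                continue
            clauses.append((node.k, frozenset(c.symptom for c in node.children)))
        else:
            raise _NotCombinatorial
    # merge identical supports, keep the strongest requirement
    merged: dict[frozenset[str], int] = {}
    for k, sup in clauses:
        merged[sup] = max(merged.get(sup, 0), k)
    out = sorted(merged.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    return [(k, sup) for sup, k in out]


@dataclass
class _Node:
    support: frozenset[str]
    k: int
    children: list["_Node"] = field(default_factory=list)

    @property
    def free(self) -> frozenset[str]:
        taken = frozenset().union(*(c.support for c in self.children)) if self.children else frozenset()
        return self.support - taken


def _laminar_forest(clauses: list[tuple[int, frozenset[str]]]) -> list[_Node]:
    """Arrange clause supports into a laminar forest; fail if not laminar."""
    for i, (_, a) in enumerate(clauses):
        for _, b in clauses[i + 1:]:
            inter = a & b
            if inter and not (a <= b or b <= a):
                raise _NotCombinatorial
    nodes = [_Node(sup, k) for k, sup in clauses]  # sorted small -> large
    roots: list[_Node] = []
    for node in nodes:
        parent = None
        for cand in nodes:
            if cand is node or not (node.support < cand.support):
                continue
            if parent is None or cand.support < parent.support:
                parent = cand
        if parent is None:
            roots.append(node)
        else:
            parent.children.append(node)
    return roots


def _min_count(node: _Node) -> int:
    """Minimum |C ∩ support| over satisfying sets C (monotone laminar system)."""
    return max(node.k, sum(_min_count(c) for c in node.children))


def _relevant_laminar(roots: list[_Node]) -> frozenset[str]:
    """Relevant symptoms of a laminar cardinality system, without enumeration.

    A symptom s is relevant iff some minimal satisfying set contains it, which
    for these systems holds iff some clause containing s can be made *tight*
    (met with equality) while s is counted toward it: min count within that
    clause's support, conditional on s being present, equals the clause's
    threshold.
    """
    relevant: set[str] = set()

    def min_with(node: _Node, s: str) -> int:
        total = 0
        in_child = False
        for c in node.children:
            if s in c.support:
                total += min_with(c, s)
                in_child = True
            else:
                total += _min_count(c)
        if not in_child:
            total += 1  # s sits among the free elements of this node
        return max(node.k, total)

    def ancestors(node: _Node, s: str, chain: list[_Node]) -> None:
        chain = chain + [node]
        for c in node.children:
            if s in c.support:
                ancestors(c, s, chain)
                return
        # innermost node containing s reached; test tightness along the chain
        for anc in chain:
            if min_with(anc, s) == anc.k and anc.k > 0:
                relevant.add(s)
                return

    for root in roots:
        for s in root.support:
            ancestors(root, s, [])
    return frozenset(relevant)


def _count_laminar(roots: list[_Node], relevant: frozenset[str]) -> int:
    """Count subsets of the relevant universe satisfying every clause.

    Works on the laminar forest with a per-node polynomial DP: poly[j] is the
    number of ways to pick j elements within the node's support (restricted to
    relevant symptoms) meeting every clause at or below the node.
    """

    def poly(node: _Node) -> list[int]:
        acc = [1]
        for c in node.children:
            cp = poly(c)
            acc = _convolve(acc, cp)
        nfree = len(node.free & relevant)
        free_poly = [comb(nfree, j) for j in range(nfree + 1)]
        acc = _convolve(acc, free_poly)
        return [(v if j >= node.k else 0) for j, v in enumerate(acc)]

    total = 1
    for root in roots:
        total *= sum(poly(root))
    return total


def _convolve(a: list[int], b: list[int]) -> list[int]:
    out = [0] * (len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        if not ai:
            continue
        for j, bj in enumerate(b):
            out[i + j] += ai * bj
    return out


def count_weakly_irredundant(
    defn: DisorderDefinition,
    mode: str = "auto",
    *,
    cap: int = DEFAULT_CAP,
) -> int:
    """Number of weakly irredundant CSSCs of a disorder.

    ``mode``:

    * ``"enumeration"`` — explicit enumeration (subject to the cap);
    * ``"combinatorial"`` — closed-form counting for conjunctions of
      cardinality clauses over plain symptoms whose supports are pairwise
      disjoint or nested (the DSM-style "k of n including j of m" shape);
      falls back to enumeration if the expression is outside that fragment;
    * ``"auto"`` — combinatorial when applicable, else enumeration.

    Both modes agree wherever both apply.
    """
    if mode not in ("auto", "enumeration", "combinatorial"):
        raise ValueError("mode must be 'auto', 'enumeration' or 'combinatorial'")
    if mode != "enumeration":
        try:
            clauses = _atleast_clauses(defn.expression)
            roots = _laminar_forest(clauses)
            relevant = _relevant_laminar(roots)
            return _count_laminar(roots, relevant)
        except _NotCombinatorial:
            pass  # fall through to enumeration
    return len(enumerate_weakly_irredundant(defn, cap=cap))


# ---------------------------------------------------------------------------
# Matrix rendering (ternary TSV)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CSSCMatrix:
    """Ternary matrix view of a CSSC set: rows = symptoms, columns = CSSCs.

    Cells are '1' (present), '0' (absent, relevant) or '?' (irrelevant for
    the disorder).  '?' rows map to 0 when exported for computation.
    """

    name: str
    symptoms: tuple[str, ...]
    columns: tuple[str, ...]
    cells: tuple[tuple[str, ...], ...]  # row-major, len(symptoms) x len(columns)

    def to_binary(self):
        """Numpy 0/1 array with '?' mapped to 0."""
        import numpy as np

        return np.array(
            [[1 if c == "1" else 0 for c in row] for row in self.cells],
            dtype=np.int8,
        )

    def to_tsv(self, path: str | Path | None = None) -> str:
        lines = ["symptom\t" + "\t".join(self.columns)]
        for s, row in zip(self.symptoms, self.cells):
            lines.append(s + "\t" + "\t".join(row))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_tsv(cls, path: str | Path, *, name: str = "") -> "CSSCMatrix":
        lines = [
            ln for ln in Path(path).read_text(encoding="utf-8").splitlines()
            if ln.strip() and not ln.startswith("#")
        ]
        header = lines[0].split("\t")
        if header[0] != "symptom":
            raise CriteriaError(f"{path}: first column must be 'symptom'")
        columns = tuple(header[1:])
        symptoms, cells = [], []
        for ln in lines[1:]:
            parts = ln.split("\t")
            if len(parts) != len(columns) + 1:
                raise CriteriaError(f"{path}: ragged row {parts[0]!r}")
            bad = set(parts[1:]) - {"0", "1", "?"}
            if bad:
                raise CriteriaError(f"{path}: invalid cells {sorted(bad)}")
            symptoms.append(parts[0])
            cells.append(tuple(parts[1:]))
        return cls(name or Path(path).stem, tuple(symptoms), columns, tuple(cells))

    def to_cssc_set(self, universe: SymptomUniverse | None = None) -> CSSCSet:
        universe = universe or SymptomUniverse(tuple(self.symptoms))
        relevant = frozenset(
            s for s, row in zip(self.symptoms, self.cells) if "?" not in row
        )
        combos = []
        for j in range(len(self.columns)):
            combos.append(
                frozenset(
                    s for s, row in zip(self.symptoms, self.cells) if row[j] == "1"
                )
            )
        return CSSCSet.from_combinations(self.name, universe, combos, relevant=relevant)


def to_matrix(
    cssc_set: CSSCSet, universe: SymptomUniverse | None = None
) -> CSSCMatrix:
    """Render a CSSC set as a ternary matrix over a (possibly larger) universe."""
    universe = universe or cssc_set.universe
    missing = frozenset(cssc_set.relevant) - frozenset(universe.symptoms)
    if missing:
        raise CriteriaError(f"universe lacks relevant symptoms: {sorted(missing)}")
    columns = tuple(f"c{j + 1}" for j in range(len(cssc_set.combinations)))
    cells = []
    for s in universe:
        if s not in cssc_set.relevant:
            cells.append(tuple("?" for _ in cssc_set.combinations))
        else:
            cells.append(
                tuple("1" if s in c else "0" for c in cssc_set.combinations)
            )
    return CSSCMatrix(cssc_set.name, tuple(universe.symptoms), columns, tuple(cells))
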