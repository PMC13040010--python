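"""Delineation tests between pairs of disorder definitions.

Two requirements decide whether a pair of disorders can, in principle, be
told apart from a symptom profile:

* **no-overlap** — the disorders share no identical weakly irredundant CSSC.
  A shared combination satisfies both definitions minimally-in-kind, so no
  further symptom assessment could ever disambiguate it.
* **no-subsumption** — no weakly irredundant CSSC of one disorder is strictly
  contained in (strict-subset mode), or criteria-satisfying for
  (criteria-satisfaction mode), the other disorder.  Subsumption is
  asymmetric and is assessed per direction.

In strict-subset mode equality of combinations counts toward overlap only
(subsumption is strict containment); in criteria-satisfaction mode a shared
CSSC trivially satisfies both definitions, making subsumption strictly weaker
than overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .criteria import CriteriaError, DisorderDefinition, evaluate
from .enumeration import CSSCSet

__all__ = [
    "OverlapResult",
    "SubsumptionResult",
    "DelineationReport",
    "check_no_overlap",
    "check_no_subsumption",
    "count_subsumption",
    "delineate",
]

MODE_SUBSET = "subset"
MODE_SATISFACTION = "satisfaction"


@dataclass(frozen=True)
class OverlapResult:
    a_name: str
    b_name: str
    witnesses: tuple[frozenset[str], ...]  # identical weakly irredundant CSSCs

    @property
    def passed(self) -> bool:
        return not self.witnesses


@dataclass(frozen=True)
class SubsumptionResult:
    """Directional subsumption witnesses for a pair, in one mode.

    In subset mode witnesses are pairs (c, d) with c a weakly irredundant
    CSSC of the *from* disorder and d one of the *to* disorder, c strictly
    contained in d (equality is overlap, not subsumption).  In satisfaction
    mode witnesses are weakly irredundant CSSCs of the *from* disorder that
    satisfy the *to* disorder's criteria; a shared identical CSSC trivially
    satisfies both, so overlap implies a satisfaction-mode violation —
    subsumption is strictly weaker than overlap.
    """

    mode: str
    a_name: str
    b_name: str
    witnesses_ab: tuple  # A subsumed by / satisfying B
    witnesses_ba: tuple

    @property
    def passed_ab(self) -> bool:
        return not self.witnesses_ab

    @property
    def passed_ba(self) -> bool:
        return not self.witnesses_ba

    @property
    def passed(self) -> bool:
        return self.passed_ab and self.passed_ba


def _check_universes(a: CSSCSet, b: CSSCSet) -> None:
    # Pairwise analyses live on the union of the two relevant sets; the only
    # hard requirement is that identically named symptoms mean the same thing,
    # which canonical ids guarantee. Distinct universes are fine.
    return None


def check_no_overlap(a: CSSCSet, b: CSSCSet) -> OverlapResult:
    """Shared identical weakly irredundant CSSCs between two disorders.

    Symmetric; disjoint relevant universes pass vacuously.  A non-empty
    witness list is equivalent to MPCS_max = 1 for the pair.
    """
    _check_universes(a, b)
    shared = set(a.combinations) & set(b.combinations)
    witnesses = tuple(sorted(shared, key=lambda c: tuple(sorted(c))))
    return OverlapResult(a.name, b.name, witnesses)


def _subset_witnesses(
    frm: CSSCSet, to: CSSCSet
) -> tuple[tuple[frozenset[str], frozenset[str]], ...]:
    out = []
    for c in frm.combinations:
        for d in to.combinations:
            if c < d:  # strict containment; equality is overlap, not subsumption
                out.append((c, d))
    return tuple(out)


def _satisfaction_witnesses(
    frm: CSSCSet, to_defn: DisorderDefinition
) -> tuple[frozenset[str], ...]:
    # Symptoms unknown to the other disorder are irrelevant for it and cannot
    # falsify a monotone rule: evaluate the restriction to its universe.
    out = []
    universe = frozenset(to_defn.universe.symptoms)
    for c in frm.combinations:
        if evaluate(to_defn, c & universe):
            out.append(c)
    return tuple(out)


def check_no_subsumption(
    a: CSSCSet,
    b: CSSCSet,
    mode: str = MODE_SUBSET,
    *,
    a_defn: DisorderDefinition | None = None,
    b_defn: DisorderDefinition | None = None,
) -> SubsumptionResult:
    """Directional subsumption test between two disorders.

    ``mode="subset"`` needs only the two CSSC sets; ``mode="satisfaction"``
    additionally needs the definitions to evaluate the other disorder's
    criteria.  For monotone criteria every subset-mode witness implies a
    satisfaction-mode witness.
    """
    _check_universes(a, b)
    if mode == MODE_SUBSET:
        return SubsumptionResult(
            mode, a.name, b.name,
            _subset_witnesses(a, b), _subset_witnesses(b, a),
        )
    if mode == MODE_SATISFACTION:
        if a_defn is None or b_defn is None:
            raise CriteriaError(
                "criteria-satisfaction mode requires both definitions"
            )
        return SubsumptionResult(
            mode, a.name, b.name,
            _satisfaction_witnesses(a, b_defn),
            _satisfaction_witnesses(b, a_defn),
        )
    raise ValueError("mode must be 'subset' or 'satisfaction'")


def count_subsumption(
    candidate: CSSCSet,
    established: CSSCSet,
    *,
    candidate_defn: DisorderDefinition | None = None,
) -> tuple[int, int, int]:
    """Subsumption counts for a candidate condition against an established one.

    Returns ``(n_sub_candidate, n_sub_established, n_total_established)``:

    * ``n_sub_candidate`` — weakly irredundant CSSCs of the candidate that are
      strict subsets of at least one weakly irredundant CSSC of the
      established disorder (each counted once);
    * ``n_sub_established`` — weakly irredundant CSSCs of the established
      disorder that satisfy the candidate's criteria (equivalently, under
      monotone criteria, supersets of at least one minimal candidate CSSC);
    * ``n_total_established`` — total weakly irredundant CSSCs of the
      established disorder.
    """
    established_combos = established.combinations
    n_sub_candidate = sum(
        1
        for c in candidate.combinations
        if any(c < d for d in established_combos)
    )
    if candidate_defn is not None:
        n_sub_established = len(
            _satisfaction_witnesses(established, candidate_defn)
        )
    else:
        minimal = candidate.irredundant or candidate.combinations
        n_sub_established = sum(
            1
            for d in established_combos
            if any(c <= d for c in minimal)
        )
    return n_sub_candidate, n_sub_established, len(established_combos)


@dataclass(frozen=True)
class DelineationReport:
    """Full pairwise delineation verdicts with witnesses and counts."""

    a_name: str
    b_name: str
    overlap: OverlapResult
    subsumption_subset: SubsumptionResult
    subsumption_satisfaction: SubsumptionResult | None
    n_sub_ab: int  # A CSSCs strictly contained in some B CSSC
    n_sub_ba: int
    n_total_a: int
    n_total_b: int

    @property
    def passed(self) -> bool:
        return self.overlap.passed and self.subsumption_subset.passed

    def to_json(self) -> dict:
        def combos(cs: Iterable[frozenset[str]]) -> list[list[str]]:
            return [sorted(c) for c in cs]

        sub = self.subsumption_subset
        out = {
            "pair": [self.a_name, self.b_name],
            "no_overlap": {
                "passed": self.overlap.passed,
                "witnesses": combos(self.overlap.witnesses),
            },
            "no_subsumption": {
                "mode": sub.mode,
                "passed": sub.passed,
                f"passed_{self.a_name}_to_{self.b_name}": sub.passed_ab,
                f"passed_{self.b_name}_to_{self.a_name}": sub.passed_ba,
                "witness_pairs_a_in_b": [
                    [sorted(c), sorted(d)] for c, d in sub.witnesses_ab
                ],
                "witness_pairs_b_in_a": [
                    [sorted(c), sorted(d)] for c, d in sub.witnesses_ba
                ],
            },
            "counts": {
                "n_sub_a": self.n_sub_ab,
                "n_sub_b": self.n_sub_ba,
                "n_total_a": self.n_total_a,
                "n_total_b": self.n_total_b,
            },
            "passed": self.passed,
        }
        if self.subsumption_satisfaction is not None:
            sat = self.subsumption_satisfaction
            out["no_subsumption_satisfaction"] = {
                "passed": sat.passed,
                "witnesses_a_satisfying_b": combos(sat.witnesses_ab),
                "witnesses_b_satisfying_a": combos(sat.witnesses_ba),
            }
        return out


def delineate(
    a: CSSCSet,
    b: CSSCSet,
    *,
    a_defn: DisorderDefinition | None = None,
    b_defn: DisorderDefinition | None = None,
) -> DelineationReport:
    """Run both delineation requirements on a pair and assemble the report.

    The headline verdict uses strict-subset subsumption; criteria-satisfaction
    counts are included whenever both definitions are supplied.
    """
    overlap = check_no_overlap(a, b)
    subset = check_no_subsumption(a, b, MODE_SUBSET)
    satisfaction = None
    if a_defn is not None and b_defn is not None:
        satisfaction = check_no_subsumption(
            a, b, MODE_SATISFACTION, a_defn=a_defn, b_defn=b_defn
        )
    n_sub_ab = sum(
        1 for c in a.combinations if any(c < d for d in b.combinations)
    )
    n_sub_ba = sum(
        1 for d in b.combinations if any(d < c for c in a.combinations)
    )
    return DelineationReport(
        a.name, b.name, overlap, subset, satisfaction,
        n_sub_ab, n_sub_ba, len(a), len(b),
    )
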