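"""No-overlap and no-subsumption checks between disorder pairs."""

import random

import pytest

from nosokit import (
    check_no_overlap,
    check_no_subsumption,
    count_subsumption,
    delineate,
    enumerate_weakly_irredundant,
    mpcs,
)
from nosokit.delineation import MODE_SATISFACTION, MODE_SUBSET
from nosokit.fixtures import RandomCriteriaSpec, random_definition


class TestOverlap:
    def test_w_x_disjoint(self, toy_sets):
        assert check_no_overlap(toy_sets["W"], toy_sets["X"]).passed

    def test_x_y_share_bd_and_bcd(self, toy_sets):
        r = check_no_overlap(toy_sets["X"], toy_sets["Y"])
        assert not r.passed
        assert {frozenset(w) for w in r.witnesses} == {
            frozenset("bd"), frozenset("bcd")}

    def test_self_comparison_fails_with_all_witnesses(self, toy_sets):
        r = check_no_overlap(toy_sets["W"], toy_sets["W"])
        assert set(r.witnesses) == set(toy_sets["W"].combinations)

    def test_symmetry(self, toy_sets):
        ab = check_no_overlap(toy_sets["X"], toy_sets["Y"])
        ba = check_no_overlap(toy_sets["Y"], toy_sets["X"])
        assert set(ab.witnesses) == set(ba.witnesses)

    def test_overlap_iff_mpcs_max_one(self, toy_sets):
        names = list(toy_sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = not check_no_overlap(toy_sets[a], toy_sets[b]).passed
                assert overlap == (
                    mpcs(toy_sets[a], toy_sets[b]).mpcs_max == 1.0)


class TestSubsumption:
    def test_z_subsumed_by_w(self, toy_sets):
        r = check_no_subsumption(toy_sets["Z"], toy_sets["W"])
        assert not r.passed_ab and r.passed_ba
        assert (frozenset("a"), frozenset("ab")) in r.witnesses_ab

    def test_z_subsumed_by_x_via_d(self, toy_sets):
        r = check_no_subsumption(toy_sets["Z"], toy_sets["X"])
        assert {c for c, _ in r.witnesses_ab} == {frozenset("d")}

    def test_w_x_pass_both_directions(self, toy_sets):
        r = check_no_subsumption(toy_sets["W"], toy_sets["X"])
        assert r.passed

    def test_equality_never_a_subset_witness(self, toy_sets):
        # identical combinations are overlap, not subsumption: every subset
        # witness must be strict, even when comparing a set with itself
        r = check_no_subsumption(toy_sets["X"], toy_sets["X"])
        assert all(c != d for c, d in r.witnesses_ab + r.witnesses_ba)
        z = check_no_subsumption(toy_sets["Z"], toy_sets["Z"])
        assert z.passed  # the singletons a, d are incomparable

    def test_satisfaction_mode_w_vs_z(self, toy_defs, toy_sets):
        r = check_no_subsumption(
            toy_sets["W"], toy_sets["Z"], MODE_SATISFACTION,
            a_defn=toy_defs["W"], b_defn=toy_defs["Z"])
        # every W CSSC contains a, hence satisfies Z's criteria
        assert set(r.witnesses_ab) == set(toy_sets["W"].combinations)

    def test_subset_witnesses_imply_satisfaction_witnesses(self, toy_defs):
        # if c in S_A is strictly contained in d in S_B, then d satisfies
        # A's criteria by monotonicity: d must be a satisfaction witness in
        # the B-to-A direction
        sets = {n: enumerate_weakly_irredundant(d) for n, d in toy_defs.items()}
        names = list(sets)
        for a in names:
            for b in names:
                if a == b:
                    continue
                sub = check_no_subsumption(sets[a], sets[b], MODE_SUBSET)
                sat = check_no_subsumption(
                    sets[a], sets[b], MODE_SATISFACTION,
                    a_defn=toy_defs[a], b_defn=toy_defs[b])
                assert {d for _, d in sub.witnesses_ab} <= set(sat.witnesses_ba)


class TestCounts:
    def test_z_candidate_against_w(self, toy_defs, toy_sets):
        n_cand, n_est, n_total = count_subsumption(
            toy_sets["Z"], toy_sets["W"], candidate_defn=toy_defs["Z"])
        assert (n_cand, n_est, n_total) == (1, 3, 3)

    def test_identical_antichain_candidate_strict_count_is_zero(self, toy_sets):
        # equality is excluded from the strict-subset count; on an antichain
        # (Z's singletons) self-comparison therefore counts nothing, while
        # the satisfaction count includes the shared combinations (overlap
        # is strictly stronger than subsumption)
        n_cand, n_est, n_total = count_subsumption(toy_sets["Z"], toy_sets["Z"])
        assert n_cand == 0
        assert n_est == n_total == len(toy_sets["Z"])

    def test_disjoint_relevant_sets_count_zero(self, toy_sets):
        from nosokit import SymptomUniverse
        from nosokit.enumeration import CSSCSet

        other = CSSCSet.from_combinations(
            "Q", SymptomUniverse(("p", "q")), [{"p"}, {"q"}])
        assert count_subsumption(other, toy_sets["W"]) == (0, 0, 3)


class TestReport:
    def test_w_x_report_passes(self, toy_defs, toy_sets):
        r = delineate(toy_sets["W"], toy_sets["X"],
                      a_defn=toy_defs["W"], b_defn=toy_defs["X"])
        assert r.passed
        doc = r.to_json()
        assert doc["passed"] and doc["no_overlap"]["passed"]

    def test_x_y_report_fails_with_witnesses(self, toy_defs, toy_sets):
        r = delineate(toy_sets["X"], toy_sets["Y"],
                      a_defn=toy_defs["X"], b_defn=toy_defs["Y"])
        assert not r.passed
        doc = r.to_json()
        assert sorted(doc["no_overlap"]["witnesses"]) == [
            ["b", "c", "d"], ["b", "d"]]


class TestOracleEquivalence:
    def test_witnesses_match_double_loop_on_random_pairs(self):
        """Subset-mode witnesses equal a brute-force double loop over all
        CSSC pairs, across seeded random definitions."""
        rng = random.Random(20240917)
        for _ in range(40):
            sa, sb = rng.randrange(10**6), rng.randrange(10**6)
            a = enumerate_weakly_irredundant(random_definition(
                RandomCriteriaSpec(n=8, n_clauses=2, seed=sa)))
            b = enumerate_weakly_irredundant(random_definition(
                RandomCriteriaSpec(n=8, n_clauses=2, seed=sb)))
            r = check_no_subsumption(a, b)
            expected = {
                (c, d) for c in a.combinations for d in b.combinations if c < d
            }
            assert set(r.witnesses_ab) == expected
            shared = set(a.combinations) & set(b.combinations)
            assert set(check_no_overlap(a, b).witnesses) == shared
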