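"""Enumeration, classification and counting of CSSCs."""

import pytest

from nosokit import (
    And,
    AtLeast,
    CriteriaError,
    DisorderDefinition,
    EnumerationCapError,
    Or,
    SymptomUniverse,
    Var,
    classify,
    count_weakly_irredundant,
    enumerate_weakly_irredundant,
    irredundant_csscs,
    relevant_symptoms,
    to_matrix,
)
from nosokit.enumeration import CSSCMatrix, CSSCSet
from nosokit.fixtures import (
    RandomCriteriaSpec,
    mdd_like_definition,
    random_definition,
)
from nosokit.oracle import brute_force_oracle


def _defn(name, expr, ids="abcd"):
    return DisorderDefinition(name, SymptomUniverse(tuple(ids)), expr)


class TestEnumerate:
    def test_toy_w(self, toy_defs):
        cssc = enumerate_weakly_irredundant(toy_defs["W"])
        assert [sorted(c) for c in cssc.combinations] == [
            ["a", "b"], ["a", "c"], ["a", "b", "c"]]
        assert cssc.relevant == frozenset("abc")

    def test_toy_x(self, toy_defs):
        cssc = enumerate_weakly_irredundant(toy_defs["X"])
        assert {frozenset(c) for c in cssc.combinations} == {
            frozenset("bd"), frozenset("cd"), frozenset("bcd")}

    def test_at_least_two_of_three(self):
        d = _defn("P", AtLeast(2, (Var("b"), Var("c"), Var("d"))))
        cssc = enumerate_weakly_irredundant(d)
        assert {frozenset(c) for c in cssc.combinations} == {
            frozenset("bc"), frozenset("bd"), frozenset("cd"), frozenset("bcd")}

    def test_cap_exceeded(self):
        ids = tuple(f"s{i}" for i in range(30))
        d = DisorderDefinition(
            "big", SymptomUniverse(ids), Or(tuple(Var(s) for s in ids)))
        with pytest.raises(EnumerationCapError, match="cap"):
            enumerate_weakly_irredundant(d, cap=24)

    def test_upward_closure_within_relevant(self, toy_defs):
        """Supersets of a weakly irredundant CSSC inside the relevant set
        are themselves weakly irredundant."""
        for defn in toy_defs.values():
            cssc = enumerate_weakly_irredundant(defn)
            members = set(cssc.combinations)
            for c in members:
                for s in cssc.relevant - c:
                    assert (c | {s}) in members


class TestIrredundant:
    def test_toy_w_minimal_sets(self, toy_defs):
        assert {frozenset(c) for c in irredundant_csscs(toy_defs["W"])} == {
            frozenset("ab"), frozenset("ac")}

    def test_toy_z_singletons(self, toy_defs):
        assert {frozenset(c) for c in irredundant_csscs(toy_defs["Z"])} == {
            frozenset("a"), frozenset("d")}

    def test_absorption(self):
        d = _defn("abs", Or((Var("a"), And((Var("a"), Var("b"))))))
        assert irredundant_csscs(d) == (frozenset("a"),)
        assert relevant_symptoms(d) == frozenset("a")

    def test_relevant_equals_union_of_minimal(self, toy_defs):
        for defn in toy_defs.values():
            minimal = irredundant_csscs(defn)
            assert relevant_symptoms(defn) == frozenset().union(*minimal)

    def test_toy_relevance(self, toy_defs):
        assert relevant_symptoms(toy_defs["W"]) == frozenset("abc")
        assert relevant_symptoms(toy_defs["X"]) == frozenset("bcd")


class TestClassify:
    @pytest.mark.parametrize("combo,expected", [
        ({"a", "b"}, {"irredundant", "weakly_irredundant"}),
        ({"a", "b", "c"}, {"weakly_irredundant", "redundant"}),
        ({"a", "b", "d"}, {"strongly_redundant", "redundant"}),
    ])
    def test_toy_w_flags(self, toy_defs, combo, expected):
        assert classify(toy_defs["W"], combo) == frozenset(expected)

    def test_non_cssc_rejected(self, toy_defs):
        with pytest.raises(CriteriaError, match="not a CSSC"):
            classify(toy_defs["W"], {"b", "c"})


class TestCount:
    def test_toy_w_count(self, toy_defs):
        assert count_weakly_irredundant(toy_defs["W"]) == 3

    def test_mdd_like_both_modes(self):
        d = mdd_like_definition()
        assert count_weakly_irredundant(d, "enumeration") == 227
        assert count_weakly_irredundant(d, "combinatorial") == 227

    def test_single_var(self):
        d = _defn("one", AtLeast(1, (Var("a"),)), ids="a")
        assert count_weakly_irredundant(d) == 1

    def test_combinatorial_handles_implied_clause(self):
        # OR(a,b) AND a: b is never in a minimal set, so only {a} is
        # weakly irredundant; the closed form must notice the irrelevance.
        d = _defn("impl", And((Or((Var("a"), Var("b"))), Var("a"))), ids="ab")
        assert count_weakly_irredundant(d, "combinatorial") == 1
        assert count_weakly_irredundant(d, "enumeration") == 1

    def test_modes_agree_on_random_laminar_definitions(self):
        for seed in range(60):
            d = random_definition(RandomCriteriaSpec(n=9, n_clauses=3, seed=seed))
            assert count_weakly_irredundant(d, "combinatorial") == \
                count_weakly_irredundant(d, "enumeration"), seed

    def test_count_matches_oracle_on_disjoint_clauses(self):
        d = _defn(
            "disjoint",
            And((AtLeast(2, (Var("a"), Var("b"), Var("c"))),
                 AtLeast(1, (Var("d"), Var("e"))))),
            ids="abcde",
        )
        expected = len(brute_force_oracle(d).weakly_irredundant)
        assert count_weakly_irredundant(d, "combinatorial") == expected == 12


class TestMatrix:
    def test_toy_w_matrix(self, toy_defs):
        m = to_matrix(enumerate_weakly_irredundant(toy_defs["W"]))
        assert m.symptoms == ("a", "b", "c", "d")
        assert m.columns == ("c1", "c2", "c3")
        assert m.cells[3] == ("?", "?", "?")  # d irrelevant
        assert m.cells[0] == ("1", "1", "1")

    def test_no_question_marks_when_all_relevant(self):
        d = _defn("P", AtLeast(2, (Var("b"), Var("c"), Var("d"))), ids="bcd")
        m = to_matrix(enumerate_weakly_irredundant(d))
        assert all("?" not in row for row in m.cells)

    def test_tsv_round_trip(self, toy_defs, tmp_path):
        cssc = enumerate_weakly_irredundant(toy_defs["W"])
        m = to_matrix(cssc)
        p = tmp_path / "w.tsv"
        m.to_tsv(p)
        again = CSSCMatrix.from_tsv(p, name="W")
        assert again.cells == m.cells
        back = again.to_cssc_set()
        assert set(back.combinations) == set(cssc.combinations)
        assert back.relevant == cssc.relevant

    def test_binary_export_maps_question_to_zero(self, toy_defs):
        m = to_matrix(enumerate_weakly_irredundant(toy_defs["W"]))
        arr = m.to_binary()
        assert arr.shape == (4, 3)
        assert arr[3].tolist() == [0, 0, 0]

    def test_explicit_combination_set_flags(self, toy_sets):
        z = toy_sets["Z"]
        assert isinstance(z, CSSCSet)
        assert all("irredundant" in z.flags[c] for c in z.combinations)
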