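"""Name normalization, checklist comparison, revision rules, UpSet counts."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ethnoassembly.taxonomy import (CanonicalName, ComparisonTable,
                                    CuratorDecision, MalformedNameError,
                                    SourceChecklist, apply_revision_rules,
                                    build_comparison, normalize_name,
                                    upset_counts)


class TestNormalizeName:
    @pytest.mark.parametrize("raw, author, binomial, flags", [
        ("Lycium  barbarum", "L.", "Lycium barbarum", set()),
        ("Lycium chinense var. potaninii", "", "Lycium chinense", {"variety"}),
        ("Lycium × intricatum", "", "Lycium intricatum", {"hybrid"}),
        ("Lycium x intricatum", "", "Lycium intricatum", {"hybrid"}),
        ("lycium BARBARUM", "", "Lycium barbarum", set()),
        ("Lycium shawii subsp. saharae", "", "Lycium shawii", {"subspecies"}),
        ("Lycium depressum f. angustifolium", "", "Lycium depressum", {"form"}),
    ])
    def test_examples(self, raw, author, binomial, flags):
        canon = normalize_name(raw, author)
        assert canon.binomial == binomial
        assert set(canon.rank_flags) == flags
        assert canon.author == author

    @pytest.mark.parametrize("raw", ["", "  ", "Lycium", "var. x"])
    def test_malformed_rejected(self, raw):
        with pytest.raises(MalformedNameError):
            normalize_name(raw)

    def test_idempotent(self):
        first = normalize_name("Lycium chinense  var. potaninii", "A.M. Lu")
        again = normalize_name(first.binomial, first.author)
        assert again.binomial == first.binomial
        assert again.author == first.author


def _cl(source_id, names, status="accepted"):
    return SourceChecklist(source_id,
                           [(n, "", status) for n in names])


class TestBuildComparison:
    def test_two_sources_sharing_one_of_three(self):
        # brute-force union of {Aa ab, Aa cd} and {Aa cd, Aa ef}: 3 rows
        table = build_comparison([
            _cl("S1", ["Aa ab", "Aa cd"]), _cl("S2", ["Aa cd", "Aa ef"])])
        assert list(table.presence.index) == ["Aa ab", "Aa cd", "Aa ef"]
        assert (table.presence.loc["Aa cd"] == "accepted").all()
        assert table.presence.loc["Aa ab", "S2"] == "absent"

    def test_identical_checklists_have_no_absent_cells(self):
        table = build_comparison([
            _cl("S1", ["Aa ab", "Aa cd"]), _cl("S2", ["Aa ab", "Aa cd"])])
        assert not (table.presence == "absent").any().any()

    def test_empty_checklist_gives_all_absent_column(self):
        table = build_comparison([_cl("S1", ["Aa ab"]), _cl("S2", [])])
        assert (table.presence["S2"] == "absent").all()

    def test_duplicate_source_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate source_id"):
            build_comparison([_cl("S1", ["Aa ab"]), _cl("S1", ["Aa cd"])])
        with pytest.raises(ValueError):
            build_comparison([])

    def test_author_conflict_flagged_not_split(self):
        table = build_comparison([
            SourceChecklist("S1", [("Aa ab", "L.", "accepted")]),
            SourceChecklist("S2", [("Aa ab", "Mill.", "accepted")])])
        assert len(table.names) == 1
        assert table.author_conflicts == {"Aa ab": {"L.", "Mill."}}

    def test_variety_row_does_not_merge_with_species(self):
        table = build_comparison([
            _cl("S1", ["Aa ab", "Aa ab var. cd"]), _cl("S2", ["Aa ab"])])
        assert len(table.names) == 2
        plain = [c for c in table.names.values() if not c.rank_flags]
        assert len(plain) == 1 and plain[0].binomial == "Aa ab"

    def test_unresolved_status_kept_distinct(self):
        table = build_comparison([
            _cl("S1", ["Aa ab"]), _cl("TPL", ["Aa ab"], status="unresolved")])
        assert table.presence.loc["Aa ab", "TPL"] == "unresolved"


class TestRevisionRules:
    def test_unanimous_name_accepted_by_rule_1(self):
        table = build_comparison([_cl(s, ["Aa ab"]) for s in "ABCD"])
        revised = apply_revision_rules(table)
        assert revised.accepted_binomials == {"Aa ab"}
        assert revised.audit["Aa ab"] == (1, "accepted")

    def test_single_source_synonym_removed_by_rule_5(self):
        table = build_comparison([
            _cl("COL", ["Aa ab"]), _cl("TPL", ["Aa ab", "Aa zz"])])
        revised = apply_revision_rules(
            table, [CuratorDecision("Aa zz", "reject_synonym")])
        assert "Aa zz" not in revised.accepted_binomials
        assert revised.audit["Aa zz"] == (5, "removed")

    def test_ten_name_toy_matches_hand_enumeration(self):
        # hand-enumerated: u0-u3 unanimous; v flagged variety; h hybrid;
        # p accepted by decision; q rejected invalid; s synonym; m queued
        everywhere = [f"Aa u{i}" for i in range(4)]
        s1 = everywhere + ["Aa vv var. x", "Aa × hh", "Aa pp", "Aa qq"]
        s2 = everywhere + ["Aa ss", "Aa mm"]
        table = build_comparison([_cl("S1", s1), _cl("S2", s2)])
        revised = apply_revision_rules(table, [
            CuratorDecision("Aa pp", "accept"),
            CuratorDecision("Aa qq", "reject_invalid"),
            CuratorDecision("Aa ss", "reject_synonym"),
        ])
        assert revised.accepted_binomials == set(everywhere) | {"Aa pp"}
        assert revised.needs_review == ["Aa mm"]
        assert revised.audit["Aa ss"] == (5, "removed")
        assert revised.audit["Aa qq"] == (4, "removed")

    def test_unknown_decision_warned_and_ignored(self):
        table = build_comparison([_cl("S1", ["Aa ab"]), _cl("S2", ["Aa ab"])])
        with pytest.warns(UserWarning, match="not in comparison table"):
            revised = apply_revision_rules(
                table, [CuratorDecision("Aa ghost", "accept")])
        assert revised.accepted_binomials == {"Aa ab"}

    def test_idempotent_on_own_output(self):
        table = build_comparison([
            _cl("S1", ["Aa ab", "Aa cd"]), _cl("S2", ["Aa ab"])])
        revised = apply_revision_rules(
            table, [CuratorDecision("Aa cd", "accept")])
        again = apply_revision_rules(build_comparison([
            _cl("Revised", sorted(revised.accepted_binomials))]))
        assert again.accepted_binomials == revised.accepted_binomials

    def test_configurable_unanimity_subset(self):
        # the rule-1 test can be restricted to a named source subset
        table = build_comparison([
            _cl("COL", ["Aa ab"]), _cl("POWO", ["Aa ab"]),
            _cl("WFO", ["Aa ab"]), _cl("TPL", [])])
        full = apply_revision_rules(table)
        assert "Aa ab" in full.needs_review
        three = apply_revision_rules(
            table, unanimity_sources=["COL", "POWO", "WFO"])
        assert three.accepted_binomials == {"Aa ab"}


class TestUpsetCounts:
    def test_two_set_toy(self):
        # membership patterns of {a,b} vs {b,c}: a->A, b->AB, c->B
        summary = upset_counts({"A": {"a", "b"}, "B": {"b", "c"}})
        assert summary.exclusive_counts == {
            frozenset({"A"}): 1, frozenset({"B"}): 1,
            frozenset({"A", "B"}): 1}
        assert summary.per_source_totals == {"A": 2, "B": 2}

    def test_identical_sets_single_cell(self):
        sets = {s: {"a", "b", "c"} for s in "ABCDE"}
        summary = upset_counts(sets)
        assert summary.exclusive_counts == {frozenset("ABCDE"): 3}

    def test_disjoint_sets_all_singletons(self):
        summary = upset_counts({"A": {"a"}, "B": {"b"}, "C": {"c"}})
        assert set(summary.exclusive_counts) == {
            frozenset({"A"}), frozenset({"B"}), frozenset({"C"})}

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            upset_counts({"A": set()})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.integers(0, 30)), min_size=1, max_size=6))
    def test_conservation(self, family):
        sets = {f"S{i}": s for i, s in enumerate(family)}
        if all(not s for s in sets.values()):
            return
        summary = upset_counts(sets)
        union = set().union(*sets.values())
        assert summary.union_size == len(union)
        for sid, s in sets.items():
            total = sum(c for pattern, c in summary.exclusive_counts.items()
                        if sid in pattern)
            assert total == len(s) == summary.per_source_totals[sid]
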