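"""Rule loading, rule matching, classification and the audit taxonomy."""

import pytest

from ecassign import chemio, fixtures
from ecassign.classify import (
    CATEGORIES,
    RuleLoadError,
    audit,
    classify_reaction,
    load_rules,
    match_rules,
)
from ecassign.diffkey import DifferenceKey, SideTaggedCode
from ecassign.pairing import KnownPairTable


def key_of(*entries) -> DifferenceKey:
    return DifferenceKey(tuple(SideTaggedCode(s, c, n) for s, c, n in entries))


class TestLoadRules:
    def test_shipped_ruleset_coverage(self, rules):
        assert len(rules.rules) >= 12
        covered = {r.sub_subclass for r in rules.rules}
        assert covered >= {
            "1.1.1", "1.2.1", "1.3.1", "1.1.3", "1.2.3", "1.5.8",
            "1.10.3", "1.14.13", "1.14.21", "1.20.4", "4.2.1", "3.6.1",
        }

    def test_one_subclass_may_own_several_keys(self, rules):
        assert sum(r.sub_subclass == "1.1.1" for r in rules.rules) >= 2

    def test_duplicate_rule_id_rejected(self, tmp_path):
        p = tmp_path / "rules.yaml"
        p.write_text(
            "rules:\n"
            "  - {id: x, sub_subclass: '1.1.1', required_s: {A1: 1}}\n"
            "  - {id: x, sub_subclass: '1.2.1', required_s: {AL: 1}}\n")
        with pytest.raises(RuleLoadError, match="duplicate"):
            load_rules(p)

    def test_empty_requirements_rejected(self, tmp_path):
        p = tmp_path / "rules.yaml"
        p.write_text("rules:\n  - {id: x, sub_subclass: '1.1.1'}\n")
        with pytest.raises(RuleLoadError, match="requirement"):
            load_rules(p)

    def test_bad_ec_prefix_rejected(self, tmp_path):
        p = tmp_path / "rules.yaml"
        p.write_text(
            "rules:\n  - {id: x, sub_subclass: '1.1', required_s: {A1: 1}}\n")
        with pytest.raises(RuleLoadError, match="sub_subclass"):
            load_rules(p)


class TestMatchRules:
    def test_worked_example_key_with_nad_context(self, rules):
        k = key_of(("S", "A1", 1), ("P", "K", 1))
        got = {r.sub_subclass
               for r in match_rules(k, frozenset({"NAD_REDOX"}), rules)}
        assert got == {"1.1.1"}

    def test_same_key_without_acceptor_context_matches_nothing(self, rules):
        k = key_of(("S", "A1", 1), ("P", "K", 1))
        assert match_rules(k, frozenset(), rules) == []

    def test_forbidden_code_blocks_rule(self, rules):
        k = key_of(("S", "C-C", 1), ("S", "O=O", 1), ("P", "C=C", 1))
        got = {r.sub_subclass
               for r in match_rules(k, frozenset({"NADP_REDOX"}), rules)}
        assert "1.3.1" not in got


class TestClassifyReaction:
    def test_worked_example_forward_single_candidate(
            self, reaction, rules, pair_table):
        res = classify_reaction(reaction("indolelactate_dh"), rules, pair_table)
        assert res.candidates == ["1.1.1"]
        assert res.direction == "forward"
        assert res.difference_key == "S:A1|P:K"

    def test_reaction_listed_backwards_matches_reversed(
            self, reaction, rules, pair_table):
        res = classify_reaction(reaction("arsenate_reductase"), rules, pair_table)
        assert res.candidates == ["1.20.4"]
        assert res.direction == "reversed"

    def test_no_donor_group_no_match(self, reaction, rules, pair_table):
        res = classify_reaction(reaction("trimethylamine_dh"), rules, pair_table)
        assert res.candidates == []
        assert res.category == "NO_MATCH"

    def test_oxo_and_hydroxyl_donor_is_ambiguous(
            self, reaction, rules, pair_table):
        res = classify_reaction(reaction("pyridoxal_dh"), rules, pair_table)
        assert res.candidates == ["1.1.1", "1.2.1"]

    def test_reversal_consistency(self, reaction, rules, pair_table):
        fwd = classify_reaction(reaction("indolelactate_dh"), rules, pair_table)
        rev = classify_reaction(reaction("indolelactate_dh").reversed(),
                                rules, pair_table)
        assert fwd.direction == "forward" and rev.direction == "reversed"
        assert fwd.candidates == rev.candidates

    def test_rule_gate_soundness(self, reaction, rules):
        """Dropping the matched rule's pair class from the table removes
        the candidate."""
        table = KnownPairTable.load()
        table.pairs = [p for p in table.pairs if p.pair_class != "NAD_REDOX"]
        res = classify_reaction(reaction("indolelactate_dh"), rules, table)
        assert "1.1.1" not in res.candidates

    def test_empty_ruleset_means_no_match_everywhere(
            self, reaction, pair_table, tmp_path):
        p = tmp_path / "rules.yaml"
        p.write_text("rules: []\n")
        empty = load_rules(p)
        for name in ("indolelactate_dh", "atp_hydrolysis"):
            res = classify_reaction(reaction(name), empty, pair_table)
            assert res.category == "NO_MATCH"


@pytest.fixture(scope="module")
def panel_results(rules, pair_table):
    from ecassign.app import run_audit

    return run_audit(fixtures.make_fixture("panel"), rules, pair_table)


class TestAudit:
    def test_expected_category_per_reaction(self, panel_results):
        results, _ = panel_results
        got = [(r.reaction, r.assigned_ec, r.category) for r in results]
        assert got == [
            ("indolelactate_dh", "1.1.1.110", "MATCH"),
            ("alcohol_dh", "1.1.1.1", "MATCH"),
            ("arsenate_reductase", "1.20.4.1", "REVERSED"),
            ("udp_murnac_dh", "1.1.1.158", "MISMATCH"),
            ("pyridoxal_dh", "1.1.1.107", "AMBIGUOUS"),
            ("sterol_demethylase", "1.14.13.70", "SIMILAR_CLASSES"),
            ("trimethylamine_dh", "1.5.8.2", "NO_MATCH"),
            ("choline_oxidase", "1.1.3.17", "MULTI_REACTION"),
            ("ring_forming_oxidase", "1.10.3", "UNCLEAR"),
            ("fumarate_hydratase", "4.2.1.2", "MATCH"),
            ("atp_hydrolysis", "3.6.1.3", "DUPLICATE_ASSIGNMENT"),
            ("atp_hydrolysis", "3.6.4.1", "DUPLICATE_ASSIGNMENT"),
        ]

    def test_mismatch_names_the_correct_class(self, panel_results):
        results, _ = panel_results
        row = next(r for r in results if r.reaction == "udp_murnac_dh")
        assert row.candidates == ["1.3.1"]

    def test_similar_classes_candidates(self, panel_results):
        results, _ = panel_results
        row = next(r for r in results if r.reaction == "sterol_demethylase")
        assert row.candidates == ["1.14.13", "1.14.21"]

    def test_category_totality(self, panel_results):
        results, summary = panel_results
        assert all(r.category in CATEGORIES for r in results)
        assert sum(summary.values()) == len(results)

    def test_audit_requires_assigned_ec(self, reaction, rules, pair_table):
        res = classify_reaction(reaction("fumarate_hydratase"), rules, pair_table)
        res.assigned_ec = None
        with pytest.raises(ValueError, match="assigned EC"):
            audit(res, rules)
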