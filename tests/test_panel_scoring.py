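"""Panel scoring: aggregation, the consensus cap on relative criteria,
and the missing-evidence policy."""

import numpy as np
import pytest

from evidem import ScoreSummary, StructuralError, ValidationError
from evidem.panel_scoring import (
    DISCERNIBLE_DISTINCTION,
    EvidenceEntry,
    ExpertScoreSheet,
    NO_SIGNIFICANT_DIFFERENCE,
    SignificanceMap,
    aggregate_scores,
    apply_missing_evidence_policy,
    read_score_summaries,
    validate_relative_rule,
    validate_relative_rule_per_expert,
    write_score_summaries,
)


def _single_criterion_sheet(scores, criterion="unmet_needs", intervention="VPZ",
                            framework=None, fill=3):
    """Panel sheet where all experts score `criterion`; every other criterion
    is filled with a constant so the sheet covers the framework."""
    experts = {}
    for i, s in enumerate(scores):
        row = {}
        for c in framework.criteria:
            row[c.id] = int(s) if c.id == criterion else fill
        experts[f"e{i}"] = {intervention: row}
    return ExpertScoreSheet(experts)


class TestAggregation:
    def test_mean_and_sample_sd(self, framework):
        sheet = _single_criterion_sheet([4, 4, 5, 4], framework=framework)
        summary = aggregate_scores(sheet, framework)["VPZ"]
        assert summary.means["unmet_needs"] == pytest.approx(4.25)
        assert summary.sds["unmet_needs"] == pytest.approx(0.5)  # n-1 denominator
        assert summary.n_experts == 4

    def test_constant_panel_has_zero_sd(self, framework):
        sheet = _single_criterion_sheet([3, 3, 3], framework=framework)
        summary = aggregate_scores(sheet, framework)["VPZ"]
        assert summary.means["unmet_needs"] == 3.0
        assert summary.sds["unmet_needs"] == 0.0

    def test_single_expert_warns_and_reports_zero_sd(self, framework):
        sheet = _single_criterion_sheet([2], framework=framework)
        with pytest.warns(UserWarning, match="single expert"):
            summary = aggregate_scores(sheet, framework)["VPZ"]
        assert summary.means["unmet_needs"] == 2.0
        assert summary.sds["unmet_needs"] == 0.0

    def test_out_of_scale_score_rejected(self, framework):
        sheet = _single_criterion_sheet([6], framework=framework)
        with pytest.raises(ValidationError, match="unmet_needs"):
            aggregate_scores(sheet, framework)

    def test_negative_score_valid_only_on_relative_criteria(self, framework):
        ok = _single_criterion_sheet([-2], criterion="intervention_costs",
                                     framework=framework)
        with pytest.warns(UserWarning):  # n = 1 panel
            summary = aggregate_scores(ok, framework)["VPZ"]
        assert summary.means["intervention_costs"] == -2.0
        bad = _single_criterion_sheet([-2], criterion="unmet_needs",
                                      framework=framework)
        with pytest.raises(ValidationError):
            aggregate_scores(bad, framework)

    def test_empty_panel_rejected(self):
        with pytest.raises(StructuralError, match="no experts"):
            ExpertScoreSheet({})

    def test_aggregation_commutes_with_expert_relabeling(self, framework):
        rng = np.random.default_rng(11)
        base = {
            f"e{i}": {
                "VPZ": {c.id: int(rng.integers(c.scale.lower, c.scale.upper + 1))
                        for c in framework.criteria}
            }
            for i in range(8)
        }
        relabeled = {f"x{i}": row for i, (_, row) in enumerate(base.items())}
        s1 = aggregate_scores(ExpertScoreSheet(base), framework)["VPZ"]
        s2 = aggregate_scores(ExpertScoreSheet(relabeled), framework)["VPZ"]
        assert s1.means == pytest.approx(s2.means)
        assert s1.sds == pytest.approx(s2.sds)
        for c in framework.criteria:
            assert c.scale.lower <= s1.means[c.id] <= c.scale.upper

    def test_csv_round_trip(self, framework, tmp_path):
        sheet = _single_criterion_sheet([1, 2, 3], framework=framework)
        path = tmp_path / "sheet.csv"
        sheet.to_csv(path)
        assert ExpertScoreSheet.from_csv(path) == sheet


class TestRelativeRule:
    def test_published_comparative_criteria_comply(self, framework, summaries):
        """All three comparative-outcome criteria were judged not significantly
        different between the drugs; their mean gaps must respect the 1-point cap."""
        sig = SignificanceMap({
            "comparative_effectiveness": NO_SIGNIFICANT_DIFFERENCE,  # 3.9 vs 3.4
            "comparative_safety": NO_SIGNIFICANT_DIFFERENCE,         # 3.0 vs 3.1
            "patient_perceived_health": NO_SIGNIFICANT_DIFFERENCE,   # 2.5 vs 2.4
        })
        violations = validate_relative_rule(
            summaries["VPZ"], summaries["TPZ"], sig, framework
        )
        assert violations == []

    def test_large_gap_flagged(self, framework, summaries):
        inflated = summaries["VPZ"].with_score("comparative_effectiveness", 5.0, 0.0)
        deflated = summaries["TPZ"].with_score("comparative_effectiveness", 2.0, 0.0)
        sig = SignificanceMap({"comparative_effectiveness": NO_SIGNIFICANT_DIFFERENCE})
        violations = validate_relative_rule(inflated, deflated, sig, framework)
        assert len(violations) == 1
        assert violations[0].difference == pytest.approx(3.0)

    def test_discernible_distinction_exempts_criterion(self, framework, summaries):
        inflated = summaries["VPZ"].with_score("comparative_effectiveness", 5.0, 0.0)
        deflated = summaries["TPZ"].with_score("comparative_effectiveness", 2.0, 0.0)
        sig = SignificanceMap({"comparative_effectiveness": DISCERNIBLE_DISTINCTION})
        assert validate_relative_rule(inflated, deflated, sig, framework) == []

    def test_exactly_one_point_gap_is_allowed(self, framework, summaries):
        a = summaries["VPZ"].with_score("comparative_safety", 4.0, 0.0)
        b = summaries["TPZ"].with_score("comparative_safety", 3.0, 0.0)
        sig = SignificanceMap({"comparative_safety": NO_SIGNIFICANT_DIFFERENCE})
        assert validate_relative_rule(a, b, sig, framework) == []

    def test_sig_map_rejects_absolute_and_unknown_criteria(self, framework):
        with pytest.raises(ValidationError, match="non-relative"):
            SignificanceMap({"unmet_needs": NO_SIGNIFICANT_DIFFERENCE}) \
                .validate_against(framework)
        with pytest.raises(StructuralError):
            SignificanceMap({"nope": NO_SIGNIFICANT_DIFFERENCE}) \
                .validate_against(framework)

    def test_per_expert_strict_mode(self, framework):
        experts = {
            "e0": {"VPZ": {}, "TPZ": {}},
            "e1": {"VPZ": {}, "TPZ": {}},
        }
        for e in experts:
            for c in framework.criteria:
                experts[e]["VPZ"][c.id] = 3
                experts[e]["TPZ"][c.id] = 3
        # one expert privately breaks the cap even though panel means comply
        experts["e0"]["VPZ"]["comparative_safety"] = 5
        experts["e1"]["VPZ"]["comparative_safety"] = 2
        experts["e0"]["TPZ"]["comparative_safety"] = 3
        experts["e1"]["TPZ"]["comparative_safety"] = 3
        sheet = ExpertScoreSheet(experts)
        sig = SignificanceMap({"comparative_safety": NO_SIGNIFICANT_DIFFERENCE})
        summaries = aggregate_scores(sheet, framework)
        assert validate_relative_rule(summaries["VPZ"], summaries["TPZ"],
                                      sig, framework) == []
        strict = validate_relative_rule_per_expert(sheet, "VPZ", "TPZ", sig, framework)
        assert [v.expert_id for v in strict] == ["e0"]


class TestMissingEvidence:
    def test_missing_for_both_drugs_zeroes_both(self, summaries):
        out = apply_missing_evidence_policy(
            {k: v.with_score("non_medical_costs", 2.0, 0.3) for k, v in summaries.items()},
            [EvidenceEntry("non_medical_costs", "no studies retrieved", "missing")],
        )
        for s in out.values():
            assert s.means["non_medical_costs"] == 0.0
            assert s.sds["non_medical_costs"] == 0.0
            assert s.annotations["non_medical_costs"] == "no-evidence"

    def test_missing_for_one_drug_leaves_other_unchanged(self, summaries):
        out = apply_missing_evidence_policy(
            summaries,
            [EvidenceEntry("other_medical_costs", "no TPZ studies", "missing",
                           intervention="TPZ")],
        )
        assert out["TPZ"].means["other_medical_costs"] == 0.0
        assert out["VPZ"].means["other_medical_costs"] == pytest.approx(1.3)

    def test_no_missing_entries_is_identity(self, summaries):
        out = apply_missing_evidence_policy(
            summaries,
            [EvidenceEntry("unmet_needs", "plenty of evidence", "high")],
        )
        assert out == dict(summaries)

    def test_unknown_quality_flag_rejected(self):
        with pytest.raises(ValidationError, match="quality"):
            EvidenceEntry("unmet_needs", "text", "excellent")


def test_summary_csv_round_trip_is_byte_identical(summaries, tmp_path):
    first = tmp_path / "a.csv"
    write_score_summaries(summaries, first)
    reread = read_score_summaries(first, n_experts=14)
    assert {k: v.means for k, v in reread.items()} == \
        {k: v.means for k, v in summaries.items()}
    assert {k: v.annotations for k, v in reread.items()} == \
        {k: v.annotations for k, v in summaries.items()}
    second = tmp_path / "b.csv"
    write_score_summaries(reread, second)
    assert first.read_bytes() == second.read_bytes()
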