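"""Rule engine: classification semantics, forward chaining, validation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from audiosem.errors import AudiosemError, ConfigurationError, SequencingError
from audiosem.features import EarFeatures, FeatureConfig, ear_profile
from audiosem.rules import (
    Rule,
    RuleBase,
    SemanticLabels,
    apply_rule_base,
    classify_laterality,
    classify_severity,
    classify_type,
    compile_condition,
    default_rule_base,
    infer_labels,
    load_rule_base,
    packaged_rule_base,
    recommend_treatment,
    save_rule_base,
    straight_line_labels,
    validate_rule_base,
)
from audiosem.vocab import SEVERITIES

from helpers import make_record


def ear(pta=10.0, conductive=False, sensorineural=False, cutoff=25.0, abg=None):
    return EarFeatures(
        pta=pta, hf_pta=pta, abg=abg, has_loss=pta > cutoff,
        ear_severity=FeatureConfig().severity_band(pta),
        conductive_evidence=conductive, sensorineural_evidence=sensorineural,
    )


class TestConditionLanguage:
    @pytest.mark.parametrize(
        "text,ctx,expected",
        [
            ("a and not b", {"a": True, "b": False}, True),
            ("x > 90", {"x": 90.0}, False),
            ("x > 90", {"x": 90.5}, True),
            ("kind in {'a', 'b'}", {"kind": "b"}, True),
            ("kind in {'a', 'b'}", {"kind": "c"}, False),
            ("(a or b) and x <= 5", {"a": False, "b": True, "x": 5.0}, True),
            ("true", {}, True),
            ("not false", {}, True),
        ],
    )
    def test_evaluation(self, text, ctx, expected):
        fn, _ = compile_condition(text)
        assert fn(ctx) is expected

    def test_referenced_names_collected(self):
        _, names = compile_condition("a and (b or c > 3) and kind == 'x'")
        assert names == {"a", "b", "c", "kind"}

    @pytest.mark.parametrize("bad", ["a &&& b", "x >", "kind in {a}", "( a"])
    def test_syntax_errors(self, bad):
        with pytest.raises(ConfigurationError):
            compile_condition(bad)


class TestClassifyType:
    def test_both_evidence_kinds_yield_mixed(self):
        assert classify_type(ear(60, conductive=True), ear(60, sensorineural=True)) == "mixed"
        assert classify_type(ear(60, conductive=True, sensorineural=True), ear(10)) == "mixed"

    def test_quiet_ears_are_normal(self):
        assert classify_type(ear(10), ear(10)) == "normal"

    def test_single_evidence_sides(self):
        assert classify_type(ear(45, conductive=True), ear(10)) == "conductive"
        assert classify_type(ear(10), ear(45, sensorineural=True)) == "sensorineural"

    def test_loss_without_evidence_defaults_to_sensorineural(self):
        assert classify_type(ear(45), ear(10)) == "sensorineural"


class TestClassifySeverity:
    @pytest.mark.parametrize("worse,expected", [(91.0, "profound"), (90.0, "severe"), (10.0, "normal")])
    def test_worse_ear_banding(self, worse, expected, config):
        assert classify_severity(ear(10.0), ear(worse), config) == expected


class TestClassifyLaterality:
    def test_decision_table(self):
        assert classify_laterality(ear(45), ear(45)) == "bilateral"
        assert classify_laterality(ear(45), ear(10)) == "unilateral_left"
        assert classify_laterality(ear(10), ear(45)) == "unilateral_right"
        assert classify_laterality(ear(10), ear(10)) == "normal"


class TestRecommendTreatment:
    @pytest.mark.parametrize(
        "hl_type,severity,laterality,expected",
        [
            ("sensorineural", "profound", "bilateral", "cochlear_implant_evaluation"),
            ("sensorineural", "severe", "bilateral", "cochlear_implant_evaluation"),
            ("sensorineural", "severe", "unilateral_left", "hearing_aid"),
            ("sensorineural", "mild", "bilateral", "hearing_aid"),
            ("conductive", "moderate", "unilateral_left", "surgical_evaluation"),
            ("mixed", "severe", "bilateral", "surgical_evaluation"),
            ("normal", "normal", "normal", "monitoring"),
        ],
    )
    def test_decision_table(self, hl_type, severity, laterality, expected):
        labels = SemanticLabels(hl_type=hl_type, severity=severity, laterality=laterality)
        assert recommend_treatment(labels) == expected

    def test_unset_upstream_labels_rejected(self):
        labels = SemanticLabels(hl_type="normal", severity="normal", laterality="normal")
        object.__setattr__(labels, "severity", "unset")
        with pytest.raises(SequencingError):
            recommend_treatment(labels)


class TestApplyRuleBase:
    def test_all_dimensions_set_with_trace(self, rule_base, config):
        record = make_record(air_level=60.0, bone_level=55.0, tymp=False)
        labels = apply_rule_base(record, rule_base, config)
        assert None not in (labels.hl_type, labels.severity, labels.laterality, labels.treatment)
        assert len(labels.trace) >= 4

    def test_trace_soundness(self, rule_base, config, noisefree_cohort):
        """Every inferred label is asserted by a fired rule in its trace."""
        records, _ = noisefree_cohort
        by_id = {r.rule_id: r for r in rule_base.rules}
        for record in records[:80]:
            labels = apply_rule_base(record, rule_base, config)
            asserted = {by_id[t].dimension: by_id[t].assertion
                        for t in labels.trace if t in by_id}
            assert asserted == {
                "type": labels.hl_type, "severity": labels.severity,
                "laterality": labels.laterality, "treatment": labels.treatment,
            }

    def test_rehabilitation_eligibility_noted(self, rule_base, config):
        record = make_record(air_level=60.0, bone_level=55.0, tymp=False)
        labels = apply_rule_base(record, rule_base, config)
        assert labels.treatment in ("hearing_aid", "cochlear_implant_evaluation")
        assert "note:auditory_rehabilitation_eligible" in labels.trace

    def test_record_order_independence(self, rule_base, config, noisy_cohort):
        records, _ = noisy_cohort
        subset = records[:40]
        forward = [apply_rule_base(r, rule_base, config) for r in subset]
        backward = [apply_rule_base(r, rule_base, config) for r in reversed(subset)]
        assert forward == list(reversed(backward))

    def test_label_invariants_on_generated_records(self, rule_base, config, noisefree_cohort):
        """normal type implies normal severity and laterality, and conversely,
        on coherent (generated) records."""
        records, _ = noisefree_cohort
        for record in records:
            labels = apply_rule_base(record, rule_base, config)
            assert (labels.hl_type == "normal") == (labels.severity == "normal")
            if labels.hl_type == "normal":
                assert labels.laterality == "normal"


def random_ear(rng, cutoff=25.0):
    pta = float(rng.uniform(0, 120))
    return EarFeatures(
        pta=pta, hf_pta=float(rng.uniform(0, 120)),
        abg=None, has_loss=pta > cutoff,
        ear_severity=FeatureConfig().severity_band(pta),
        conductive_evidence=bool(rng.random() < 0.3),
        sensorineural_evidence=bool(rng.random() < 0.3),
    )


def test_engine_matches_straight_line_reimplementation(rule_base, config):
    """Forward chaining agrees with the non-engine classifiers on 10,000
    random ear-feature pairs, across all four dimensions."""
    rng = np.random.default_rng(2024)
    for _ in range(10_000):
        left, right = random_ear(rng), random_ear(rng)
        engine = infer_labels(left, right, rule_base)
        direct = straight_line_labels(left, right, config)
        assert (engine.hl_type, engine.severity, engine.laterality, engine.treatment) == (
            direct.hl_type, direct.severity, direct.laterality, direct.treatment)


@given(st.floats(0, 110), st.floats(0, 110), st.floats(0, 10))
def test_severity_never_decreases_when_thresholds_rise(left_pta, right_pta, delta):
    config = FeatureConfig()
    base = classify_severity(ear(left_pta), ear(right_pta), config)
    worse = classify_severity(ear(left_pta + delta), ear(right_pta + delta), config)
    assert SEVERITIES.index(worse) >= SEVERITIES.index(base)


class TestValidateRuleBase:
    def test_shipped_base_is_total_exclusive_and_reachable(self, rule_base, config):
        report = validate_rule_base(rule_base, config)
        assert report.passed
        assert report.exhaustiveness_violations == []
        assert report.exclusivity_violations == []
        assert report.unreachable_rules == []

    def test_gutted_severity_family_reported(self, rule_base, config):
        kept = tuple(r for r in rule_base.rules
                     if r.dimension != "severity" or r.rule_id == "severity_profound")
        report = validate_rule_base(RuleBase(rules=kept), config, pta_step=5)
        missing = [v for v in report.exhaustiveness_violations if v[0] == "severity"]
        assert missing
        assert all(max(v[1]["left_pta"], v[1]["right_pta"]) <= 90 for v in missing)

    def test_equal_priority_contradiction_reported(self, rule_base, config):
        extra = (
            Rule("dup_a", "type", 5, "conductive_any", "conductive"),
            Rule("dup_b", "type", 5, "conductive_any", "mixed"),
        )
        report = validate_rule_base(RuleBase(rules=extra + rule_base.rules),
                                    config, pta_step=10)
        assert any(v[0] == "type" and set(v[1]) == {"dup_a", "dup_b"}
                   for v in report.exclusivity_violations)


class TestRuleBaseSerialization:
    def test_bit_exact_round_trip(self, rule_base, tmp_path):
        text = save_rule_base(rule_base)
        reloaded = load_rule_base(text)
        assert reloaded == rule_base
        assert save_rule_base(reloaded) == text
        path = tmp_path / "rules.txt"
        save_rule_base(rule_base, path)
        assert load_rule_base(path) == rule_base

    def test_packaged_file_matches_programmatic_default(self):
        assert packaged_rule_base() == default_rule_base()

    def test_missing_dimension_rejected(self):
        with pytest.raises(ConfigurationError, match="no rule for dimension"):
            RuleBase(rules=(Rule("only", "type", 1, "true", "normal"),))
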