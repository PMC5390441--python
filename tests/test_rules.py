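"""Rule evaluation, registry round-trips, and ROC cutoff calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from harmonizer.metadata import Dtype, Scale, VariableMetadata
from harmonizer.rules import (
    CutoffResult,
    RegistrySchemaError,
    Rule,
    RuleKind,
    TargetDefinition,
    TargetRegistry,
    calibrate_registry,
    evaluate_rule,
    evaluate_ruleset,
    load_registry,
    optimize_cutoff,
    registry_from_dict,
    save_registry,
)
from harmonizer.pipeline import GoldMapping

from _oracles import brute_cutoff


def meta(name="x", label=None, dtype=Dtype.NUMBER, scale=Scale.RATIO,
         n_values=10, prop=0.2, median=None, iqr=None, n=10):
    return VariableMetadata(
        name=name, label=label, dtype=dtype, scale=scale, n_values=n_values,
        prop_most_frequent=prop, median=median, iqr=iqr, n_nonmissing=n,
    )


class TestEvaluateRule:
    def test_name_substring_case_insensitive(self):
        rule = Rule("r", RuleKind.NAME_CONTAINS, pattern="cholesterol")
        assert evaluate_rule(rule, meta(name="serum_CHOLESTEROL_mgdl"))
        assert not evaluate_rule(rule, meta(name="hdl_chol"))

    def test_median_threshold(self):
        rule = Rule("r", RuleKind.THRESHOLD, feature="median", direction="gt", cutoff=94)
        assert evaluate_rule(rule, meta(median=121.0))
        assert not evaluate_rule(rule, meta(median=80.0))

    def test_absent_feature_is_false_not_error(self):
        rule = Rule("r", RuleKind.THRESHOLD, feature="median", direction="gt", cutoff=94)
        string_var = meta(dtype=Dtype.STRING, scale=Scale.NOMINAL)
        assert evaluate_rule(rule, string_var) is False

    def test_absent_label_is_false(self):
        rule = Rule("r", RuleKind.LABEL_CONTAINS, pattern="age")
        assert evaluate_rule(rule, meta(label=None)) is False
        assert evaluate_rule(rule, meta(label="Age at baseline"))

    def test_dtype_and_scale_equality(self):
        assert evaluate_rule(Rule("r", RuleKind.DTYPE_IS, pattern="number"), meta())
        assert not evaluate_rule(Rule("r", RuleKind.SCALE_IS, pattern="ordinal"), meta())

    def test_accent_insensitive(self):
        rule = Rule("r", RuleKind.NAME_CONTAINS, pattern="glycémie")
        assert evaluate_rule(rule, meta(name="GLYCEMIE_a_jeun"))

    def test_malformed_rules_rejected(self):
        with pytest.raises(ValueError):
            Rule("r", RuleKind.THRESHOLD, feature="median", direction="between", cutoff=1)
        with pytest.raises(ValueError):
            Rule("r", RuleKind.NAME_CONTAINS)  # no pattern
        with pytest.raises(ValueError):
            Rule("r", RuleKind.NAME_CONTAINS, pattern="x", cutoff=4.0)


def test_ruleset_vector_follows_rule_order():
    target = TargetDefinition(
        "Age", "years",
        [Rule("a", RuleKind.NAME_CONTAINS, pattern="age"),
         Rule("b", RuleKind.DTYPE_IS, pattern="number")],
    )
    assert evaluate_ruleset(target, meta(name="AGE")).tolist() == [True, True]
    string_var = meta(name="sex", dtype=Dtype.STRING, scale=Scale.NOMINAL)
    assert evaluate_ruleset(target, string_var).tolist() == [False, False]


class TestOptimizeCutoff:
    def test_separated_classes(self):
        result = optimize_cutoff([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1], "gt")
        assert result == CutoffResult(6.5, 1.0, 1.0)

    def test_tie_broken_by_smallest_cutoff(self):
        result = optimize_cutoff([1, 4, 2, 5], [0, 0, 1, 1], "gt")
        assert result.cutoff == 1.5
        assert result.sensitivity + result.specificity == pytest.approx(1.5)

    def test_single_pair(self):
        result = optimize_cutoff([0.0, 1.0], [0, 1], "gt")
        assert result.sensitivity == 1.0 and result.specificity == 1.0

    def test_lt_direction(self):
        result = optimize_cutoff([1, 2, 10, 11], [1, 1, 0, 0], "lt")
        assert result.cutoff == 6.0
        assert result.sensitivity == 1.0 and result.specificity == 1.0

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="identical"):
            optimize_cutoff([1, 2, 3], [1, 1, 1], "gt")

    @pytest.mark.parametrize("direction", ["gt", "lt"])
    def test_exhaustive_small_grid_matches_bruteforce(self, direction):
        """Every value pattern over {0,1,2} x every non-constant labelling, n<=5."""
        for n in (2, 3, 4, 5):
            for values in itertools.product([0.0, 1.0, 2.0], repeat=n):
                for labels in itertools.product([0, 1], repeat=n):
                    if len(set(labels)) < 2:
                        continue
                    ours = optimize_cutoff(values, labels, direction)
                    cutoff, sens, spec = brute_cutoff(values, labels, direction)
                    assert ours.cutoff == cutoff
                    assert ours.sensitivity == pytest.approx(sens)
                    assert ours.specificity == pytest.approx(spec)

    @settings(max_examples=150, derandomize=True)
    @given(
        st.lists(st.integers(min_value=-50, max_value=50), min_size=2, max_size=12),
        st.data(),
    )
    def test_matches_bruteforce_and_permutation_invariant(self, values, data):
        labels = data.draw(
            st.lists(st.booleans(), min_size=len(values), max_size=len(values))
        )
        if len(set(labels)) < 2:
            labels[0], labels[-1] = True, False
        values = [float(v) for v in values]
        ours = optimize_cutoff(values, labels, "gt")
        cutoff, sens, spec = brute_cutoff(values, labels, "gt")
        assert (ours.cutoff, ours.sensitivity, ours.specificity) == (cutoff, pytest.approx(sens), pytest.approx(spec))
        # permutation invariance
        order = data.draw(st.permutations(range(len(values))))
        permuted = optimize_cutoff([values[i] for i in order], [labels[i] for i in order], "gt")
        assert permuted == ours
        # never worse than any observed value used as a cutoff
        for observed in values:
            pred = [v > observed for v in values]
            tp = sum(p and l for p, l in zip(pred, labels))
            tn = sum((not p) and (not l) for p, l in zip(pred, labels))
            n_pos = sum(labels)
            objective = tp / n_pos + tn / (len(labels) - n_pos)
            assert ours.sensitivity + ours.specificity >= objective - 1e-12

    def test_shifting_positives_up_cannot_hurt(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        labels[0] = True
        labels[1] = False
        base = optimize_cutoff(values, labels, "gt")
        shifted = values + np.where(labels, 2.0, 0.0)
        better = optimize_cutoff(shifted, labels, "gt")
        assert (
            better.sensitivity + better.specificity
            >= base.sensitivity + base.specificity - 1e-12
        )


class TestRegistry:
    def test_default_registry_shape(self, registry):
        assert len(registry) == 41
        sbp = registry.get("Systolic blood pressure")
        assert sbp.unit == "mmHg"
        assert any(
            r.kind is RuleKind.THRESHOLD and r.cutoff == 94 for r in sbp.rules
        )

    def test_round_trip(self, registry, tmp_path):
        path = tmp_path / "registry.yaml"
        save_registry(registry, path)
        assert load_registry(path) == registry

    def test_empty_targets_is_schema_error(self):
        with pytest.raises(RegistrySchemaError):
            registry_from_dict({"schema_version": 1, "targets": []})

    def test_all_schema_errors_reported_together(self):
        doc = {
            "targets": [
                {"name": "A", "rules": [{"id": "r", "kind": "nope", "pattern": "x"}]},
                {"unit": "mg", "rules": [{"id": "r", "kind": "dtype_is", "pattern": "number"}]},
                {"name": "B", "rules": []},
            ]
        }
        with pytest.raises(RegistrySchemaError) as excinfo:
            registry_from_dict(doc)
        message = str(excinfo.value)
        assert "unknown rule kind" in message
        assert "missing required field 'name'" in message
        assert "'B'" in message  # the empty-rules target is reported too

    def test_duplicate_targets_rejected(self):
        target = {"name": "A", "unit": "", "rules": [{"id": "r", "kind": "name_contains", "pattern": "a"}]}
        with pytest.raises(RegistrySchemaError, match="duplicate"):
            registry_from_dict({"targets": [target, dict(target)]})


def test_calibration_recovers_separating_cutoff():
    """A threshold rule re-fitted on labelled profiles lands between the classes."""
    target = TargetDefinition(
        "Systolic blood pressure", "mmHg",
        [Rule("sbp_thr", RuleKind.THRESHOLD, feature="median", direction="gt", cutoff=0.0)],
    )
    registry = TargetRegistry([target])
    profiles = {
        "D1": [meta(name="sbp", median=130.0), meta(name="weight", median=70.0)],
        "D2": [meta(name="sys_bp", median=135.0), meta(name="height", median=170.0)],
    }
    gold = [
        GoldMapping("D1", "sbp", "Systolic blood pressure"),
        GoldMapping("D2", "sys_bp", "Systolic blood pressure"),
    ]
    calibrated = registry_from_dict  # noqa: F841 (keep name spellable)
    new = calibrate_registry(registry, profiles, gold)
    cutoff = new.get("Systolic blood pressure").rules[0].cutoff
    assert 70.0 < cutoff < 130.0


def test_calibration_keeps_rule_when_uncalibratable(caplog):
    target = TargetDefinition(
        "Age", "years",
        [Rule("thr", RuleKind.THRESHOLD, feature="median", direction="gt", cutoff=30.0)],
    )
    registry = TargetRegistry([target])
    profiles = {"D1": [meta(name="age", median=50.0)]}
    new = calibrate_registry(registry, profiles, [])  # no positives at all
    assert new.get("Age").rules[0].cutoff == 30.0
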