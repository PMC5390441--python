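"""Per-target allocation rules: the binary predicates that become logic-tree leaves.

A rule is a simple, total predicate on a variable's metadata profile — e.g.
"'cholesterol' occurs in the variable name", "the variable is numeric", or
"the median exceeds 94". Each target variable of the uniform dataset owns an
ordered rule set; evaluating a rule set on one source variable yields the
binary leaf-input vector for the logic-regression engine.

Threshold rules carry a cutoff that can be calibrated on labelled training
data by maximizing sensitivity + specificity over an ROC scan.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .metadata import VariableMetadata, Dtype, Scale, normalize_text

logger = logging.getLogger("harmonizer")

SCHEMA_VERSION = 1

__all__ = [
    "RuleKind",
    "Rule",
    "TargetDefinition",
    "TargetRegistry",
    "RegistrySchemaError",
    "evaluate_rule",
    "evaluate_ruleset",
    "optimize_cutoff",
    "CutoffResult",
    "load_registry",
    "save_registry",
    "default_registry",
    "calibrate_registry",
]


class RuleKind(str, enum.Enum):
    NAME_CONTAINS = "name_contains"
    LABEL_CONTAINS = "label_contains"
    DTYPE_IS = "dtype_is"
    SCALE_IS = "scale_is"
    THRESHOLD = "threshold"


_SUBSTRING_KINDS = {RuleKind.NAME_CONTAINS, RuleKind.LABEL_CONTAINS}
_THRESHOLD_FEATURES = ("median", "iqr", "n_values", "prop_most_frequent")


@dataclass(frozen=True)
class Rule:
    """One binary predicate on :class:`~harmonizer.metadata.VariableMetadata`.

    Substring kinds carry ``pattern``; ``dtype_is``/``scale_is`` carry
    ``pattern`` naming the level; threshold kinds carry ``feature``,
    ``direction`` ('gt'/'lt') and ``cutoff``. Evaluation is total: a rule
    whose feature is absent from the profile evaluates false.
    """

    id: str
    kind: RuleKind
    pattern: Optional[str] = None
    feature: Optional[str] = None
    direction: Optional[str] = None
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind is RuleKind.THRESHOLD:
            if self.pattern is not None:
                raise ValueError(f"rule {self.id}: threshold rules carry no pattern")
            if self.feature not in _THRESHOLD_FEATURES:
                raise ValueError(
                    f"rule {self.id}: feature must be one of {_THRESHOLD_FEATURES}"
                )
            if self.direction not in ("gt", "lt"):
                raise ValueError(f"rule {self.id}: direction must be 'gt' or 'lt'")
            if self.cutoff is None:
                raise ValueError(f"rule {self.id}: threshold rules need a cutoff")
        else:
            if self.pattern is None:
                raise ValueError(f"rule {self.id}: {self.kind.value} rules need a pattern")
            if self.feature is not None or self.cutoff is not None or self.direction is not None:
                raise ValueError(
                    f"rule {self.id}: feature/direction/cutoff are threshold-only fields"
                )


def evaluate_rule(rule: Rule, meta: VariableMetadata) -> bool:
    """Evaluate one rule on one variable profile. Never raises on data.

    Substring matching is case- and accent-insensitive; an absent label makes
    any ``label_contains`` rule false; an absent numeric feature makes any
    threshold rule false.
    """
    if rule.kind is RuleKind.NAME_CONTAINS:
        return normalize_text(rule.pattern) in normalize_text(meta.name)
    if rule.kind is RuleKind.LABEL_CONTAINS:
        if meta.label is None:
            return False
        return normalize_text(rule.pattern) in normalize_text(meta.label)
    if rule.kind is RuleKind.DTYPE_IS:
        return meta.dtype is Dtype(rule.pattern)
    if rule.kind is RuleKind.SCALE_IS:
        return meta.scale is Scale(rule.pattern)
    # threshold
    value = meta.feature(rule.feature)
    if value is None:
        return False
    return value > rule.cutoff if rule.direction == "gt" else value < rule.cutoff


@dataclass
class TargetDefinition:
    """A target variable of the uniform dataset plus its ordered rule set."""

    target_name: str
    unit: str
    rules: list[Rule]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError(f"target {self.target_name!r}: needs at least one rule")
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError(f"target {self.target_name!r}: duplicate rule ids")

    @property
    def rule_ids(self) -> list[str]:
        return [r.id for r in self.rules]


def evaluate_ruleset(target: TargetDefinition, meta: VariableMetadata) -> np.ndarray:
    """Binary leaf-input vector: element i is rules[i] evaluated on ``meta``."""
    return np.array([evaluate_rule(r, meta) for r in target.rules], dtype=bool)


@dataclass
class TargetRegistry:
    """The full set of target definitions (the role of the curated rule table)."""

    targets: list[TargetDefinition]

    def __post_init__(self) -> None:
        names = [t.target_name for t in self.targets]
        if len(set(names)) != len(names):
            raise ValueError("duplicate target names in registry")

    def __len__(self) -> int:
        return len(self.targets)

    def __iter__(self):
        return iter(self.targets)

    def get(self, name: str) -> TargetDefinition:
        for t in self.targets:
            if t.target_name == name:
                return t
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [t.target_name for t in self.targets]


class RegistrySchemaError(ValueError):
    """Raised on invalid registry files; carries every offence, not just the first."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid registry: " + "; ".join(self.errors))


def _rule_from_dict(raw: Mapping, context: str, errors: list[str]) -> Optional[Rule]:
    kind_text = raw.get("kind")
    try:
        kind = RuleKind(kind_text)
    except ValueError:
        errors.append(f"{context}: unknown rule kind {kind_text!r}")
        return None
    try:
        return Rule(
            id=str(raw.get("id", "")),
            kind=kind,
            pattern=raw.get("pattern"),
            feature=raw.get("feature"),
            direction=raw.get("direction"),
            cutoff=None if raw.get("cutoff") is None else float(raw["cutoff"]),
        )
    except (ValueError, TypeError) as exc:
        errors.append(f"{context}: {exc}")
        return None


def registry_from_dict(data: Mapping) -> TargetRegistry:
    """Build and validate a registry from parsed YAML/JSON, collecting all errors."""
    errors: list[str] = []
    if not isinstance(data, Mapping):
        raise RegistrySchemaError(["registry document must be a mapping"])
    raw_targets = data.get("targets")
    if not raw_targets:
        raise RegistrySchemaError(["registry must define a non-empty 'targets' list"])
    targets: list[TargetDefinition] = []
    seen: set[str] = set()
    for i, raw in enumerate(raw_targets):
        name = raw.get("name")
        context = f"target[{i}] ({name!r})"
        if not name:
            errors.append(f"{context}: missing required field 'name'")
            continue
        if name in seen:
            errors.append(f"{context}: duplicate target name")
            continue
        seen.add(name)
        rules = []
        for j, raw_rule in enumerate(raw.get("rules") or []):
            rule = _rule_from_dict(raw_rule, f"{context}.rules[{j}]", errors)
            if rule is not None:
                rules.append(rule)
        if not rules:
            errors.append(f"{context}: needs at least one valid rule")
            continue
        try:
            targets.append(
                TargetDefinition(target_name=name, unit=str(raw.get("unit", "")), rules=rules)
            )
        except ValueError as exc:
            errors.append(f"{context}: {exc}")
    if errors:
        raise RegistrySchemaError(errors)
    return TargetRegistry(targets=targets)


def registry_to_dict(registry: TargetRegistry) -> dict:
    targets = []
    for t in registry:
        rules = []
        for r in t.rules:
            entry: dict = {"id": r.id, "kind": r.kind.value}
            if r.pattern is not None:
                entry["pattern"] = r.pattern
            if r.feature is not None:
                entry["feature"] = r.feature
                entry["direction"] = r.direction
                entry["cutoff"] = r.cutoff
            rules.append(entry)
        targets.append({"name": t.target_name, "unit": t.unit, "rules": rules})
    return {"schema_version": SCHEMA_VERSION, "targets": targets}


def load_registry(path: Union[str, Path]) -> TargetRegistry:
    """Load a registry from YAML (JSON is a YAML subset and is accepted too)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return registry_from_dict(data)


def save_registry(registry: TargetRegistry, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(registry_to_dict(registry), fh, sort_keys=False, allow_unicode=True)


def default_registry() -> TargetRegistry:
    """The packaged registry of 41 target variables with reconstructed rules.

    The original curated per-target rule table is not public; the packaged
    rules are authored from the targets' names, units and plausible value
    ranges, and are meant as a realistic default, not a replica.
    """
    from importlib.resources import files

    text = files("harmonizer.data").joinpath("registry.yaml").read_text(encoding="utf-8")
    return registry_from_dict(yaml.safe_load(text))


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float


def optimize_cutoff(
    feature_values: Sequence[float],
    labels: Sequence[int],
    direction: str,
) -> CutoffResult:
    """ROC scan for the cutoff maximizing sensitivity + specificity.

    Candidate cutoffs are the midpoints between consecutive sorted distinct
    feature values plus -inf/+inf sentinels; ties in the objective are broken
    by the smallest cutoff. ``direction='gt'`` predicts positive when the
    feature strictly exceeds the cutoff, ``'lt'`` when it falls strictly
    below.
    """
    values = np.asarray(feature_values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if values.shape != y.shape or values.ndim != 1:
        raise ValueError("feature_values and labels must be equal-length 1-D sequences")
    if direction not in ("gt", "lt"):
        raise ValueError("direction must be 'gt' or 'lt'")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("cannot calibrate a cutoff: all labels are identical")

    distinct = np.unique(values)
    midpoints = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(([-np.inf], midpoints, [np.inf]))

    # vectorized confusion counts at every candidate
    if direction == "gt":
        pred = values[None, :] > candidates[:, None]
    else:
        pred = values[None, :] < candidates[:, None]
    tp = (pred & y[None, :]).sum(axis=1)
    tn = (~pred & ~y[None, :]).sum(axis=1)
    # sens+spec compared in exact integer arithmetic (common denominator
    # n_pos*n_neg) so ties break deterministically on the smallest cutoff
    objective = tp * n_neg + tn * n_pos
    best = int(np.argmax(objective))  # first occurrence = smallest candidate
    return CutoffResult(
        cutoff=float(candidates[best]),
        sensitivity=float(tp[best]) / n_pos,
        specificity=float(tn[best]) / n_neg,
    )


def calibrate_registry(
    registry: TargetRegistry,
    profiles_by_dataset: Mapping[str, Sequence[VariableMetadata]],
    gold: Iterable,
) -> TargetRegistry:
    """Re-fit every threshold rule's cutoff on labelled training profiles.

    ``gold`` is an iterable of objects with ``dataset_id``, ``source_variable``
    and ``target_name`` attributes (see :mod:`harmonizer.pipeline`). Profiles
    lacking the rule's feature are excluded from that rule's calibration; an
    uncalibratable rule (single class, or no usable feature values) keeps its
    authored cutoff with a warning.
    """
    positives: dict[str, set[tuple[str, str]]] = {}
    for m in gold:
        positives.setdefault(m.target_name, set()).add((m.dataset_id, m.source_variable))

    new_targets = []
    for target in registry:
        pos = positives.get(target.target_name, set())
        new_rules = []
        for rule in target.rules:
            if rule.kind is not RuleKind.THRESHOLD:
                new_rules.append(rule)
                continue
            values, labels = [], []
            for ds_id, profiles in profiles_by_dataset.items():
                for meta in profiles:
                    value = meta.feature(rule.feature)
                    if value is None:
                        continue
                    values.append(value)
                    labels.append((ds_id, meta.name) in pos)
            try:
                result = optimize_cutoff(values, labels, rule.direction)
            except ValueError as exc:
                logger.warning(
                    "target %r rule %r: cutoff kept at %s (%s)",
                    target.target_name, rule.id, rule.cutoff, exc,
                )
                new_rules.append(rule)
                continue
            new_rules.append(replace(rule, cutoff=result.cutoff))
        new_targets.append(
            TargetDefinition(target_name=target.target_name, unit=target.unit, rules=new_rules)
        )
    return TargetRegistry(targets=new_targets)
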