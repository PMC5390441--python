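"""End-to-end supervised allocation: instances, per-target fits, ranking, reporting.

Supervision comes from a gold mapping table (dataset, source variable →
target). For each target, every (dataset, variable) pair becomes one training
instance: its features are the target's rule outputs on the variable's
metadata profile, its label is whether the gold standard maps that variable to
the target. One logic tree is fitted per target; applied to a new dataset it
flags candidate source variables, which are ranked by the fraction of
satisfied leaves so a reviewer sees a short list rather than a bare yes/no.

Performance is reported per target as sensitivity, specificity, PPV and NPV
in a construction and a validation sample, with an unweighted Average row —
the layout of the published summary table, which also ships as a packaged
fixture for aggregation checks.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .logictree import (
    AnnealingConfig,
    FitResult,
    LogicTree,
    anneal,
    evaluate_tree_matrix,
    parse_expression,
    satisfied_leaf_fraction,
    tree_to_expression,
)
from .metadata import VariableMetadata
from .rules import TargetDefinition, TargetRegistry, evaluate_ruleset, registry_from_dict, registry_to_dict

logger = logging.getLogger("harmonizer")

__all__ = [
    "GoldMapping",
    "ConfusionMetrics",
    "AllocationCandidate",
    "TargetInstances",
    "read_gold",
    "write_gold",
    "build_instances",
    "fit_all_targets",
    "allocate",
    "compute_metrics",
    "evaluate_models",
    "pooled_metrics",
    "metrics_frame",
    "performance_report",
    "load_table1",
    "load_table2",
    "read_manifest",
    "resplit_manifest",
    "models_to_dict",
    "models_from_dict",
    "save_models",
    "load_models",
]


@dataclass(frozen=True)
class GoldMapping:
    """One manually harmonized allocation: dataset + source variable → target."""

    dataset_id: str
    source_variable: str
    target_name: str


def read_gold(path: Union[str, Path]) -> list[GoldMapping]:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["dataset_id", "source_variable", "target_name"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"gold mapping file lacks columns: {missing}")
    return [
        GoldMapping(row.dataset_id, row.source_variable, row.target_name)
        for row in frame.itertuples()
    ]


def write_gold(gold: Sequence[GoldMapping], path: Union[str, Path]) -> None:
    pd.DataFrame(
        [(g.dataset_id, g.source_variable, g.target_name) for g in gold],
        columns=["dataset_id", "source_variable", "target_name"],
    ).to_csv(path, index=False)


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts with the four derived rates (None when undefined).

    Sensitivity is the portion of matching source variables correctly
    identified; specificity the portion of non-matching ones identified as
    such; PPV/NPV the portion of positive/negative identifications that are
    correct. A rate whose denominator is zero is None.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def _ratio(num: int, denom: int) -> Optional[float]:
        return num / denom if denom else None

    @property
    def sensitivity(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> Optional[float]:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> Optional[float]:
        return self._ratio(self.tn, self.tn + self.fn)

    def __add__(self, other: "ConfusionMetrics") -> "ConfusionMetrics":
        return ConfusionMetrics(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )


def compute_metrics(predictions: Sequence[int], labels: Sequence[int]) -> ConfusionMetrics:
    pred = np.asarray(predictions, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels must have equal length")
    return ConfusionMetrics(
        tp=int((pred & y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
        tn=int((~pred & ~y).sum()),
    )


@dataclass
class TargetInstances:
    """Labelled rule matrix for one target over all (dataset, variable) pairs."""

    target_name: str
    rule_ids: list[str]
    matrix: np.ndarray  # (instances x rules) bool
    labels: np.ndarray  # (instances,) bool
    groups: list[str]  # source dataset id per instance
    pairs: list[tuple[str, str]]  # (dataset_id, variable name) per instance

    def subset(self, dataset_ids: Iterable[str]) -> "TargetInstances":
        keep_ids = set(dataset_ids)
        mask = np.array([g in keep_ids for g in self.groups], dtype=bool)
        return TargetInstances(
            target_name=self.target_name,
            rule_ids=self.rule_ids,
            matrix=self.matrix[mask],
            labels=self.labels[mask],
            groups=[g for g, m in zip(self.groups, mask) if m],
            pairs=[p for p, m in zip(self.pairs, mask) if m],
        )


def _validate_gold(
    profiles_by_dataset: Mapping[str, Sequence[VariableMetadata]],
    registry: TargetRegistry,
    gold: Sequence[GoldMapping],
) -> None:
    errors = []
    names = set(registry.names)
    seen_pairs: set[tuple[str, str]] = set()
    for g in gold:
        if g.target_name not in names:
            errors.append(f"gold target {g.target_name!r} not in registry")
        key = (g.dataset_id, g.target_name)
        if key in seen_pairs:
            errors.append(f"duplicate gold mapping for {key}")
        seen_pairs.add(key)
        profiles = profiles_by_dataset.get(g.dataset_id)
        if profiles is None:
            errors.append(f"gold references unknown dataset {g.dataset_id!r}")
        elif g.source_variable not in {p.name for p in profiles}:
            errors.append(
                f"gold references {g.dataset_id}/{g.source_variable}, "
                "absent from that dataset's profiles"
            )
    if errors:
        raise ValueError("invalid gold mappings: " + "; ".join(errors))


def build_instances(
    profiles_by_dataset: Mapping[str, Sequence[VariableMetadata]],
    registry: TargetRegistry,
    gold: Sequence[GoldMapping],
) -> dict[str, TargetInstances]:
    """Turn profiled datasets plus gold mappings into per-target labelled matrices.

    Every (dataset, variable) pair is one instance of every target; its label
    is positive only for the target the gold standard maps it to, so a
    variable mapped to target A is a negative instance of target B.
    """
    _validate_gold(profiles_by_dataset, registry, gold)
    positives: dict[str, set[tuple[str, str]]] = {}
    for g in gold:
        positives.setdefault(g.target_name, set()).add((g.dataset_id, g.source_variable))

    out: dict[str, TargetInstances] = {}
    for target in registry:
        rows, labels, groups, pairs = [], [], [], []
        pos = positives.get(target.target_name, set())
        for ds_id, profiles in profiles_by_dataset.items():
            for meta in profiles:
                rows.append(evaluate_ruleset(target, meta))
                labels.append((ds_id, meta.name) in pos)
                groups.append(ds_id)
                pairs.append((ds_id, meta.name))
        out[target.target_name] = TargetInstances(
            target_name=target.target_name,
            rule_ids=target.rule_ids,
            matrix=np.array(rows, dtype=bool),
            labels=np.array(labels, dtype=bool),
            groups=groups,
            pairs=pairs,
        )
    return out


def _target_seed(base_seed: int, target_index: int) -> int:
    # stable per-target stream, independent of which other targets are fitted
    return int(np.random.SeedSequence([base_seed, target_index]).generate_state(1)[0] % (2**31))


def fit_all_targets(
    instances: Mapping[str, TargetInstances],
    config: AnnealingConfig,
) -> dict[str, FitResult]:
    """Fit one logic tree per target; targets without positives are skipped."""
    fits: dict[str, FitResult] = {}
    for i, (name, inst) in enumerate(instances.items()):
        if not inst.labels.any():
            logger.warning("target %r has no positive instances; skipped", name)
            continue
        target_config = AnnealingConfig(
            method=config.method,
            weights=config.weights,
            treesize=config.treesize,
            minmass=config.minmass,
            p_start=config.p_start,
            p_end=config.p_end,
            n_iterations=config.n_iterations,
            seed=_target_seed(config.seed, i),
        )
        fits[name] = anneal(inst.matrix, inst.labels, target_config)
    return fits


@dataclass(frozen=True)
class AllocationCandidate:
    """One ranked suggestion: a source variable proposed for a target."""

    dataset_id: str
    target_name: str
    source_variable: str
    predicted: bool
    rank_key: float


def allocate(
    fits: Mapping[str, FitResult],
    registry: TargetRegistry,
    profiles: Sequence[VariableMetadata],
    top_k: int = 5,
    dataset_id: str = "",
    ranked: bool = True,
) -> dict[str, list[AllocationCandidate]]:
    """Rank candidate source variables of one dataset for every fitted target.

    All predicted-positive variables are returned (sorted by rank key
    descending, name ascending on ties); when they number fewer than
    ``top_k``, the best-ranked negatives fill the list — the escape hatch for
    the case that the tree missed the true variable entirely. With
    ``ranked=False`` the rank key is the bare 0/1 prediction.
    """
    out: dict[str, list[AllocationCandidate]] = {}
    for name, fit in fits.items():
        target = registry.get(name)
        candidates = []
        for meta in profiles:
            vector = evaluate_ruleset(target, meta)
            predicted = bool(evaluate_tree_matrix(fit.best_tree, vector[None, :])[0])
            key = satisfied_leaf_fraction(fit.best_tree, vector) if ranked else float(predicted)
            candidates.append(
                AllocationCandidate(
                    dataset_id=dataset_id,
                    target_name=name,
                    source_variable=meta.name,
                    predicted=predicted,
                    rank_key=key,
                )
            )
        candidates.sort(key=lambda c: (-c.rank_key, c.source_variable))
        positives = [c for c in candidates if c.predicted]
        negatives = [c for c in candidates if not c.predicted]
        selected = positives + negatives[: max(0, top_k - len(positives))]
        selected.sort(key=lambda c: (-c.rank_key, c.source_variable))
        out[name] = selected
    return out


def evaluate_models(
    fits: Mapping[str, FitResult],
    instances: Mapping[str, TargetInstances],
) -> dict[str, ConfusionMetrics]:
    """Per-target confusion metrics of fitted trees on a set of instances."""
    out = {}
    for name, fit in fits.items():
        inst = instances[name]
        preds = evaluate_tree_matrix(fit.best_tree, inst.matrix)
        out[name] = compute_metrics(preds, inst.labels)
    return out


def pooled_metrics(per_target: Mapping[str, ConfusionMetrics]) -> ConfusionMetrics:
    """Micro-average: confusion counts summed over targets."""
    total = ConfusionMetrics(0, 0, 0, 0)
    for m in per_target.values():
        total = total + m
    return total


# ---------------------------------------------------------------------------
# reporting

_METRIC_COLUMNS = [
    "construction_sensitivity",
    "construction_specificity",
    "construction_ppv",
    "construction_npv",
    "validation_sensitivity",
    "validation_specificity",
    "validation_ppv",
    "validation_npv",
]


def metrics_frame(
    construction: Mapping[str, Optional[ConfusionMetrics]],
    validation: Mapping[str, Optional[ConfusionMetrics]],
) -> pd.DataFrame:
    """Assemble the per-target 8-column metric table from confusion metrics."""
    rows = []
    for name in construction.keys() | validation.keys():
        row: dict[str, object] = {"target": name}
        for sample, metrics in (("construction", construction.get(name)),
                                ("validation", validation.get(name))):
            for metric in ("sensitivity", "specificity", "ppv", "npv"):
                value = getattr(metrics, metric) if metrics is not None else None
                row[f"{sample}_{metric}"] = np.nan if value is None else value
        rows.append(row)
    frame = pd.DataFrame(rows, columns=["target"] + _METRIC_COLUMNS)
    return frame.sort_values("target", kind="stable").reset_index(drop=True)


def performance_report(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Append the unweighted Average row and summarize low-PPV prevalence.

    The Average of each metric column is the plain arithmetic mean over
    targets, excluding missing cells. The summary reports, for each sample,
    the fraction of targets whose PPV is 0.5 or less (missing PPV excluded
    from numerator and denominator).
    """
    if "target" not in frame.columns:
        raise ValueError("report frame needs a 'target' column")
    body = frame[frame["target"] != "Average"].copy()
    averages: dict[str, object] = {"target": "Average"}
    for col in _METRIC_COLUMNS:
        averages[col] = body[col].mean(skipna=True) if col in body else np.nan
    extra = [c for c in body.columns if c not in averages]
    for c in extra:
        averages[c] = ""
    report = pd.concat([body, pd.DataFrame([averages])], ignore_index=True)
    summary = {}
    for sample in ("construction", "validation"):
        ppv = body[f"{sample}_ppv"].dropna()
        summary[f"{sample}_ppv_le_0.5"] = float((ppv <= 0.5).mean()) if len(ppv) else np.nan
    return report, summary


def _fixture_path(name: str):
    from importlib.resources import files

    return files("harmonizer.data").joinpath(name)


def load_table2() -> pd.DataFrame:
    """Packaged per-target performance fixture (41 targets, 8 metric columns)."""
    with _fixture_path("table2.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_table1() -> pd.DataFrame:
    """Packaged dataset manifest fixture (34 cohort datasets with their split)."""
    with _fixture_path("table1.csv").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def read_manifest(path: Union[str, Path]) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"acronym", "use"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    uses = set(frame["use"].unique()) - {"Construction", "Validation"}
    if uses:
        raise ValueError(f"manifest 'use' must be Construction/Validation, found {sorted(uses)}")
    return frame


def resplit_manifest(manifest: pd.DataFrame, seed: int, ratio: float = 0.5) -> pd.DataFrame:
    """Randomly re-assign datasets to construction/validation at the given ratio.

    Construction receives ceil(n * ratio) datasets; the packaged fixture keeps
    the published split, this reproduces the random 1:1 assignment procedure.
    """
    rng = np.random.default_rng(seed)
    out = manifest.copy().reset_index(drop=True)
    order = rng.permutation(len(out))
    n_construction = int(np.ceil(len(out) * ratio))
    use = np.array(["Validation"] * len(out), dtype=object)
    use[order[:n_construction]] = "Construction"
    out["use"] = use
    return out


# ---------------------------------------------------------------------------
# model bundle serialization


def models_to_dict(
    fits: Mapping[str, FitResult], registry: TargetRegistry
) -> dict:
    """Self-contained JSON-ready bundle: registry plus one expression per target."""
    models = {}
    for name, fit in fits.items():
        target = registry.get(name)
        models[name] = {
            "rule_ids": target.rule_ids,
            "expression": tree_to_expression(fit.best_tree, target.rule_ids),
            "best_score": fit.best_score,
            "config": {
                "method": fit.config.method.value,
                "w_pos": fit.config.weights.w_pos,
                "w_neg": fit.config.weights.w_neg,
                "treesize": fit.config.treesize,
                "minmass": fit.config.minmass,
                "p_start": fit.config.p_start,
                "p_end": fit.config.p_end,
                "n_iterations": fit.config.n_iterations,
                "seed": fit.config.seed,
            },
        }
    return {"registry": registry_to_dict(registry), "models": models}


def models_from_dict(data: Mapping) -> tuple[dict[str, FitResult], TargetRegistry]:
    from .logictree import Method, ScoreWeights

    registry = registry_from_dict(data["registry"])
    fits: dict[str, FitResult] = {}
    for name, model in data["models"].items():
        config_data = model["config"]
        config = AnnealingConfig(
            method=Method(config_data["method"]),
            weights=ScoreWeights(config_data["w_pos"], config_data["w_neg"]),
            treesize=config_data["treesize"],
            minmass=config_data["minmass"],
            p_start=config_data["p_start"],
            p_end=config_data["p_end"],
            n_iterations=config_data["n_iterations"],
            seed=config_data["seed"],
        )
        tree = parse_expression(model["expression"], model["rule_ids"])
        fits[name] = FitResult(
            best_tree=tree,
            best_score=float(model["best_score"]),
            score_trace=[],
            n_accepted_moves=0,
            config=config,
        )
    return fits, registry


def save_models(fits: Mapping[str, FitResult], registry: TargetRegistry, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(models_to_dict(fits, registry), fh, indent=2)


def load_models(path: Union[str, Path]) -> tuple[dict[str, FitResult], TargetRegistry]:
    with open(path, "r", encoding="utf-8") as fh:
        return models_from_dict(json.load(fh))
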