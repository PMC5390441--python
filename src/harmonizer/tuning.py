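"""Tuning of the annealing parameters: factorial design, grouped CV, selection.

The operating configuration (scoring method, negative-class weight, tree
size, minimum mass) is chosen by evaluating a full factorial design — the
published grid is 2 methods x 4 negative weights x 2 tree sizes x 2 minimum
masses = 32 runs — under k-fold cross-validation, then picking the point that
maximizes sensitivity subject to floors on sensitivity (99%) and specificity
(75%). Because logic trees latch onto dataset-specific naming conventions,
folds are grouped by source dataset by default: all variables of one cohort
share a fold.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .logictree import AnnealingConfig, Method, ScoreWeights, anneal, evaluate_tree_matrix
from .pipeline import ConfusionMetrics, compute_metrics, pooled_metrics

logger = logging.getLogger("harmonizer")

__all__ = [
    "DesignPoint",
    "DesignResult",
    "DEFAULT_DESIGN_LEVELS",
    "generate_design",
    "cross_validate",
    "CVResult",
    "run_design",
    "select_config",
    "SelectionResult",
    "main_effects",
]


#: The published tuning grid: 2 x 4 x 2 x 2 = 32 design points.
DEFAULT_DESIGN_LEVELS: dict[str, tuple] = {
    "method": (Method.CLASSIFICATION, Method.LOGISTIC),
    "w_neg": (5e-4, 5e-3, 5e-2, 5e-1),
    "treesize": (5, 10),
    "minmass": (4, 8),
}

_FACTOR_ORDER = ("method", "w_neg", "treesize", "minmass")


@dataclass(frozen=True)
class DesignPoint:
    """One configuration of the factorial tuning study."""

    method: Method
    w_neg: float
    treesize: int
    minmass: int

    def to_config(self, base: AnnealingConfig) -> AnnealingConfig:
        """Materialize as an AnnealingConfig, inheriting schedule/seed from ``base``."""
        return AnnealingConfig(
            method=self.method,
            weights=ScoreWeights.from_w_neg(self.w_neg),
            treesize=self.treesize,
            minmass=self.minmass,
            p_start=base.p_start,
            p_end=base.p_end,
            n_iterations=base.n_iterations,
            seed=base.seed,
        )

    def sort_key(self) -> tuple:
        return (self.method.value, self.w_neg, self.treesize, self.minmass)


def generate_design(levels: Mapping[str, Sequence] | None = None) -> list[DesignPoint]:
    """Full Cartesian product of factor levels, in deterministic lexicographic order.

    Factors iterate in the fixed order method, w_neg, treesize, minmass, each
    over its level sequence as given. The default levels reproduce the
    published 32-run grid.
    """
    levels = dict(levels) if levels is not None else dict(DEFAULT_DESIGN_LEVELS)
    missing = [f for f in _FACTOR_ORDER if f not in levels]
    if missing:
        raise ValueError(f"missing factors: {missing}")
    for factor in _FACTOR_ORDER:
        if len(levels[factor]) == 0:
            raise ValueError(f"factor {factor!r} has no levels")
    points = [
        DesignPoint(
            method=Method(m), w_neg=float(w), treesize=int(t), minmass=int(mm)
        )
        for m, w, t, mm in itertools.product(*(levels[f] for f in _FACTOR_ORDER))
    ]
    return points


@dataclass
class CVResult:
    """Per-fold and pooled confusion metrics of one cross-validated configuration."""

    fold_metrics: list[ConfusionMetrics]
    pooled: ConfusionMetrics

    def mean_sensitivity(self) -> Optional[float]:
        values = [m.sensitivity for m in self.fold_metrics if m.sensitivity is not None]
        return float(np.mean(values)) if values else None

    def mean_specificity(self) -> Optional[float]:
        values = [m.specificity for m in self.fold_metrics if m.specificity is not None]
        return float(np.mean(values)) if values else None


def _fold_assignment(
    groups: Sequence[str], k: int, grouped: bool, rng: np.random.Generator
) -> np.ndarray:
    """Fold index per instance; grouped mode keeps each dataset in one fold."""
    n = len(groups)
    if grouped:
        unique = sorted(set(groups))
        if len(unique) < k:
            raise ValueError(
                f"grouped {k}-fold CV needs at least {k} datasets, got {len(unique)}"
            )
        order = rng.permutation(len(unique))
        fold_of_group = {unique[g]: i % k for i, g in enumerate(order)}
        return np.array([fold_of_group[g] for g in groups], dtype=int)
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return folds


def cross_validate(
    matrix: np.ndarray,
    labels: Sequence[int],
    groups: Sequence[str],
    config: AnnealingConfig,
    k: int = 10,
    grouped: bool = True,
    seed: int = 0,
) -> CVResult:
    """k-fold cross-validation of one annealing configuration.

    Each fold is predicted by a tree fitted on the remaining folds, so every
    instance is predicted exactly once. A fold without positives has
    undefined sensitivity; it is reported as None and excluded from fold
    means with a warning. Fold assignment and per-fold fits are fully
    determined by ``seed``.
    """
    matrix = np.asarray(matrix, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds = _fold_assignment(list(groups), k, grouped, rng)

    fold_metrics: list[ConfusionMetrics] = []
    for fold in range(k):
        test = folds == fold
        train = ~test
        if not test.any():
            continue
        if not y[train].any():
            logger.warning("fold %d: training split has no positives; fold skipped", fold)
            continue
        fold_seed = int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))
        fold_config = AnnealingConfig(
            method=config.method,
            weights=config.weights,
            treesize=config.treesize,
            minmass=config.minmass,
            p_start=config.p_start,
            p_end=config.p_end,
            n_iterations=config.n_iterations,
            seed=fold_seed,
        )
        fit = anneal(matrix[train], y[train], fold_config)
        preds = evaluate_tree_matrix(fit.best_tree, matrix[test])
        metrics = compute_metrics(preds, y[test])
        if metrics.sensitivity is None:
            logger.warning("fold %d has no positive instances; sensitivity undefined", fold)
        fold_metrics.append(metrics)

    pooled = ConfusionMetrics(0, 0, 0, 0)
    for m in fold_metrics:
        pooled = pooled + m
    return CVResult(fold_metrics=fold_metrics, pooled=pooled)


@dataclass
class DesignResult:
    """Cross-validated sensitivity/specificity of one design point.

    Headline sensitivity/specificity are pooled (micro-averaged) over folds;
    the per-fold metrics are kept for dispersion checks.
    """

    point: DesignPoint
    sensitivity: float
    specificity: float
    fold_metrics: list[ConfusionMetrics]

    def __post_init__(self) -> None:
        for value in (self.sensitivity, self.specificity):
            if not (np.isnan(value) or 0.0 <= value <= 1.0):
                raise ValueError("metrics must lie in [0, 1]")


def run_design(
    points: Sequence[DesignPoint],
    matrix: np.ndarray,
    labels: Sequence[int],
    groups: Sequence[str],
    base: AnnealingConfig,
    k: int = 10,
    grouped: bool = True,
    seed: int = 0,
) -> list[DesignResult]:
    """Cross-validate every design point on one target's labelled instances."""
    results = []
    for point in points:
        cv = cross_validate(
            matrix, labels, groups, point.to_config(base), k=k, grouped=grouped, seed=seed
        )
        sens = cv.pooled.sensitivity
        spec = cv.pooled.specificity
        results.append(
            DesignResult(
                point=point,
                sensitivity=np.nan if sens is None else sens,
                specificity=np.nan if spec is None else spec,
                fold_metrics=cv.fold_metrics,
            )
        )
    return results


def run_design_suite(
    points: Sequence[DesignPoint],
    instances: Mapping[str, "object"],
    base: AnnealingConfig,
    k: int = 10,
    grouped: bool = True,
    seed: int = 0,
) -> list[DesignResult]:
    """Cross-validate every design point over all targets, pooling counts.

    ``instances`` maps target name to a labelled instance set (see
    :class:`harmonizer.pipeline.TargetInstances`); targets without positives
    are skipped. Each design point's sensitivity/specificity micro-average
    over every fold of every target.
    """
    results = []
    for point in points:
        pooled = ConfusionMetrics(0, 0, 0, 0)
        folds: list[ConfusionMetrics] = []
        for name, inst in instances.items():
            if not inst.labels.any():
                continue
            cv = cross_validate(
                inst.matrix, inst.labels, inst.groups,
                point.to_config(base), k=k, grouped=grouped, seed=seed,
            )
            pooled = pooled + cv.pooled
            folds.extend(cv.fold_metrics)
        sens = pooled.sensitivity
        spec = pooled.specificity
        results.append(
            DesignResult(
                point=point,
                sensitivity=np.nan if sens is None else sens,
                specificity=np.nan if spec is None else spec,
                fold_metrics=folds,
            )
        )
    return results


@dataclass(frozen=True)
class SelectionResult:
    """Chosen design point plus how far the floors had to be relaxed.

    relaxation 0: both floors met; 1: only the specificity floor could be
    met; 2: unconstrained maximum sensitivity.
    """

    point: DesignPoint
    sensitivity: float
    specificity: float
    relaxation: int


def select_config(
    results: Sequence[DesignResult],
    sens_floor: float = 0.99,
    spec_floor: float = 0.75,
) -> SelectionResult:
    """Constrained selection: maximize sensitivity under the two floors.

    Among points meeting both floors the one with maximal sensitivity wins,
    ties broken by specificity then by lexicographic factor order. If no
    point meets both floors, the sensitivity floor is dropped first, then the
    specificity floor; the relaxation level is reported.
    """
    if not results:
        raise ValueError("no design results to select from")

    def pick(candidates: Sequence[DesignResult]) -> DesignResult:
        return min(
            candidates,
            key=lambda r: (-r.sensitivity, -r.specificity, r.point.sort_key()),
        )

    usable = [r for r in results if not (np.isnan(r.sensitivity) or np.isnan(r.specificity))]
    if not usable:
        raise ValueError("all design results have undefined metrics")
    tiers = [
        (0, [r for r in usable if r.sensitivity >= sens_floor and r.specificity >= spec_floor]),
        (1, [r for r in usable if r.specificity >= spec_floor]),
        (2, usable),
    ]
    for relaxation, candidates in tiers:
        if candidates:
            if relaxation:
                logger.warning("selection floors relaxed to level %d", relaxation)
            chosen = pick(candidates)
            return SelectionResult(
                point=chosen.point,
                sensitivity=chosen.sensitivity,
                specificity=chosen.specificity,
                relaxation=relaxation,
            )
    raise AssertionError("unreachable")


def main_effects(results: Sequence[DesignResult]) -> pd.DataFrame:
    """Mean pooled sensitivity/specificity per factor level (main-effect summary)."""
    rows = []
    for r in results:
        rows.append(
            {
                "method": r.point.method.value,
                "w_neg": r.point.w_neg,
                "treesize": r.point.treesize,
                "minmass": r.point.minmass,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
        )
    frame = pd.DataFrame(rows)
    effects = []
    for factor in _FACTOR_ORDER:
        grouped = frame.groupby(factor)[["sensitivity", "specificity"]].mean()
        for level, row in grouped.iterrows():
            effects.append(
                {
                    "factor": factor,
                    "level": level,
                    "mean_sensitivity": row["sensitivity"],
                    "mean_specificity": row["specificity"],
                }
            )
    return pd.DataFrame(effects, columns=["factor", "level", "mean_sensitivity", "mean_specificity"])


def design_results_frame(results: Sequence[DesignResult]) -> pd.DataFrame:
    """One row per design point with its pooled metrics (the 32-run table)."""
    return pd.DataFrame(
        [
            {
                "method": r.point.method.value,
                "w_neg": r.point.w_neg,
                "treesize": r.point.treesize,
                "minmass": r.point.minmass,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
            }
            for r in results
        ]
    )
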