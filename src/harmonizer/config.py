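"""Run configuration, defaults, logging and provenance.

A run configuration collects everything a pipeline invocation needs — file
locations, the annealing block, cross-validation and selection settings, and
the master seed. It loads from YAML (JSON accepted), fills documented
defaults, validates exhaustively (every violation reported, not just the
first), and serializes alongside every output so results are reproducible
bit for bit.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .logictree import AnnealingConfig, Method, ScoreWeights

logger = logging.getLogger("harmonizer")

__all__ = ["RunConfig", "load_config", "config_to_dict", "write_provenance", "setup_logging"]

#: Documented defaults: negative-class weight 0.0005 (positives 0.9995),
#: schedule 0.1 -> 0.0001, 10-fold grouped CV, floors 99% / 75%.
DEFAULTS = {
    "registry": None,
    "data_dir": None,
    "manifest": None,
    "gold": None,
    "out_dir": ".",
    "seed": 0,
    "top_k": 5,
    "annealing": {
        "method": "classification",
        "w_neg": 0.0005,
        "treesize": 5,
        "minmass": 4,
        "p_start": 0.1,
        "p_end": 0.0001,
        "n_iterations": 50_000,
    },
    "cv": {"k": 10, "grouped": True},
    "selection": {"sens_floor": 0.99, "spec_floor": 0.75},
}


@dataclass
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    registry: Optional[str] = None
    data_dir: Optional[str] = None
    manifest: Optional[str] = None
    gold: Optional[str] = None
    out_dir: str = "."
    seed: int = 0
    top_k: int = 5
    annealing: AnnealingConfig = field(default_factory=AnnealingConfig)
    cv_k: int = 10
    cv_grouped: bool = True
    sens_floor: float = 0.99
    spec_floor: float = 0.75


def _merge(defaults: Mapping, overrides: Mapping) -> dict:
    merged = dict(defaults)
    for key, value in overrides.items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), Mapping):
            merged[key] = _merge(merged[key], value)
        else:
            merged[key] = value
    return merged


def load_config(path: Optional[Union[str, Path]] = None, overrides: Optional[Mapping] = None) -> RunConfig:
    """Load a RunConfig from YAML/JSON, fill defaults, validate exhaustively.

    ``overrides`` (e.g. parsed CLI flags) take precedence over file values,
    which take precedence over defaults. Unknown keys and invalid values are
    all reported together.
    """
    data: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, Mapping):
                raise ValueError("config document must be a mapping")
            data = dict(loaded)

    merged = _merge(DEFAULTS, data)
    if overrides:
        merged = _merge(merged, {k: v for k, v in overrides.items() if v is not None})

    errors = []
    known = set(DEFAULTS)
    for key in merged:
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    ann = merged["annealing"]
    for key in ann:
        if key not in DEFAULTS["annealing"] and key != "seed":
            errors.append(f"unknown annealing key {key!r}")
    if ann["method"] not in ("classification", "logistic"):
        errors.append(f"annealing.method must be classification/logistic, got {ann['method']!r}")
    if not (0 < float(ann["w_neg"]) < 1):
        errors.append("annealing.w_neg must lie in (0, 1)")
    if int(ann["treesize"]) < 1:
        errors.append("annealing.treesize must be >= 1")
    if int(ann["minmass"]) < 0:
        errors.append("annealing.minmass must be >= 0")
    if not (float(ann["p_start"]) > float(ann["p_end"]) > 0):
        errors.append("annealing schedule requires p_start > p_end > 0")
    if int(ann["n_iterations"]) < 1:
        errors.append("annealing.n_iterations must be >= 1")
    if int(merged["cv"]["k"]) < 2:
        errors.append("cv.k must be >= 2")
    for floor_key in ("sens_floor", "spec_floor"):
        value = float(merged["selection"][floor_key])
        if not 0 <= value <= 1:
            errors.append(f"selection.{floor_key} must lie in [0, 1]")
    if errors:
        raise ValueError("invalid configuration: " + "; ".join(errors))

    annealing = AnnealingConfig(
        method=Method(ann["method"]),
        weights=ScoreWeights.from_w_neg(float(ann["w_neg"])),
        treesize=int(ann["treesize"]),
        minmass=int(ann["minmass"]),
        p_start=float(ann["p_start"]),
        p_end=float(ann["p_end"]),
        n_iterations=int(ann["n_iterations"]),
        seed=int(ann.get("seed", merged["seed"])),
    )
    return RunConfig(
        registry=merged["registry"],
        data_dir=merged["data_dir"],
        manifest=merged["manifest"],
        gold=merged["gold"],
        out_dir=str(merged["out_dir"]),
        seed=int(merged["seed"]),
        top_k=int(merged["top_k"]),
        annealing=annealing,
        cv_k=int(merged["cv"]["k"]),
        cv_grouped=bool(merged["cv"]["grouped"]),
        sens_floor=float(merged["selection"]["sens_floor"]),
        spec_floor=float(merged["selection"]["spec_floor"]),
    )


def config_to_dict(config: RunConfig) -> dict:
    data = asdict(config)
    data["annealing"] = {
        "method": config.annealing.method.value,
        "w_pos": config.annealing.weights.w_pos,
        "w_neg": config.annealing.weights.w_neg,
        "treesize": config.annealing.treesize,
        "minmass": config.annealing.minmass,
        "p_start": config.annealing.p_start,
        "p_end": config.annealing.p_end,
        "n_iterations": config.annealing.n_iterations,
        "seed": config.annealing.seed,
    }
    return data


def write_provenance(out_dir: Union[str, Path], config: RunConfig, command: str) -> Path:
    """Write the provenance block (resolved config, seed, package version)."""
    from . import __version__

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "command": command,
        "package_version": __version__,
        "seed": config.seed,
        "config": config_to_dict(config),
        "written_at": datetime.now(timezone.utc).isoformat(),
    }
    path = out / "provenance.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
    return path


class _JsonLineHandler(logging.FileHandler):
    def emit(self, record: logging.LogRecord) -> None:
        record.msg = json.dumps(
            {"level": record.levelname, "message": record.getMessage()}
        )
        record.args = ()
        logging.FileHandler.emit(self, record)


def setup_logging(run_log: Optional[Union[str, Path]] = None, level: int = logging.INFO) -> None:
    """Log human-readably to stderr, machine-readably (JSON lines) to ``run_log``."""
    root = logging.getLogger("harmonizer")
    root.setLevel(level)
    root.handlers = [logging.StreamHandler(sys.stderr)]
    if run_log is not None:
        root.addHandler(_JsonLineHandler(str(run_log)))
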