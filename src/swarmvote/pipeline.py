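"""End-to-end run configuration and orchestration.

A run fits ensemble weights on the declared prediction/label files, applies
the weighted combination, evaluates it, and writes three artifacts:
``weights.json``, ``ensemble.csv`` and ``report.json``.  All inputs are
read and validated before any output is written, so a failing stage leaves
no partial results.  The seed and a hash of the full configuration are
echoed into the weight file so a run can be replayed exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as svio
from .ensemble import combine
from .errors import ValidationError
from .metrics import report as metrics_report
from .pso import PSOConfig, optimize_weights

logger = logging.getLogger(__name__)

_PSO_FIELDS = {f.name for f in dataclasses.fields(PSOConfig)}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full pipeline run."""

    predictions: tuple[str, ...]
    labels: str
    out_dir: str = "."
    class_names: tuple[str, ...] | None = None
    pso: PSOConfig = field(default_factory=PSOConfig)
    kernel_size: int = 9
    margin: int = 0
    averaging: str = "macro"
    log_level: str = "INFO"


def _reject_unknown(section: dict, allowed: set[str], where: str) -> None:
    unknown = sorted(set(section) - allowed)
    if unknown:
        raise ValidationError(f"unknown {where} keys: {unknown}")


def load_config(path: str | Path, seed: int | None = None) -> RunConfig:
    """Parse a YAML run configuration; unknown keys are rejected.

    Layout::

        io:
          predictions: [m1.csv, m2.csv]
          labels: y.csv
          out_dir: results/
          class_names: [glioma, meningioma, pituitary]   # optional
        pso: {n_particles: 100, max_iterations: 1000, ...}
        preprocessing: {kernel_size: 9, margin: 0}
        metrics: {averaging: macro}
        log_level: INFO

    ``seed`` (e.g. from the CLI) overrides ``pso.seed``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    _reject_unknown(raw, {"io", "pso", "preprocessing", "metrics", "log_level"}, "config")
    io_sec = raw.get("io", {})
    _reject_unknown(io_sec, {"predictions", "labels", "out_dir", "class_names"}, "io")
    if "predictions" not in io_sec or "labels" not in io_sec:
        raise ValidationError("config io section must declare predictions and labels")
    pso_sec = dict(raw.get("pso", {}))
    _reject_unknown(pso_sec, _PSO_FIELDS, "pso")
    if seed is not None:
        pso_sec["seed"] = seed
    pre = raw.get("preprocessing", {})
    _reject_unknown(pre, {"kernel_size", "margin"}, "preprocessing")
    met = raw.get("metrics", {})
    _reject_unknown(met, {"averaging"}, "metrics")
    if met.get("averaging", "macro") != "macro":
        raise ValidationError("only macro averaging is supported")
    cfg = RunConfig(
        predictions=tuple(str(p) for p in io_sec["predictions"]),
        labels=str(io_sec["labels"]),
        out_dir=str(io_sec.get("out_dir", ".")),
        class_names=tuple(io_sec["class_names"]) if io_sec.get("class_names") else None,
        pso=PSOConfig(**pso_sec),
        kernel_size=int(pre.get("kernel_size", 9)),
        margin=int(pre.get("margin", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    for p in cfg.predictions + (cfg.labels,):
        if not Path(p).exists():
            raise ValidationError(f"input path does not exist: {p}")
    return cfg


def config_hash(cfg: RunConfig) -> str:
    payload = dataclasses.asdict(cfg)
    return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Fit weights, combine, evaluate; returns the report dict.

    Stages are named in any raised error so failures are attributable.
    """
    logger.info("run config hash %s, seed %d", config_hash(cfg), cfg.pso.seed)
    try:
        preds = svio.read_predictions(cfg.predictions)
        labels, label_ids = svio.read_labels(cfg.labels, cfg.class_names)
        y = svio.align_labels(labels, label_ids, preds)
    except Exception as exc:
        raise type(exc)(f"[read-inputs] {exc}") from exc

    try:
        weights, loss, trace = optimize_weights(preds, y, cfg.pso)
    except Exception as exc:
        raise type(exc)(f"[optimize-weights] {exc}") from exc

    try:
        combined = combine(preds, weights)
        rep = metrics_report(y, combined, cfg.class_names)
    except Exception as exc:
        raise type(exc)(f"[evaluate] {exc}") from exc

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    svio.write_weights(
        out / "weights.json",
        preds.model_ids,
        weights,
        loss=loss,
        extra={
            "seed": cfg.pso.seed,
            "config": dataclasses.asdict(cfg.pso),
            "config_hash": config_hash(cfg),
            "trace": [float(v) for v in trace],
        },
    )
    svio.write_predictions_csv(out / "ensemble.csv", preds.sample_ids, combined)
    svio.write_report(out / "report.json", rep.to_dict())
    logger.info("wrote weights.json, ensemble.csv, report.json to %s", out)
    return rep.to_dict()
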