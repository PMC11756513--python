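"""End-to-end orchestration: normalize, assemble, split, tune, fit, call, score.

The one-shot :func:`run_train_eval` reproduces the full study flow on a pair
of trace/label files; :func:`run_predict` applies a persisted model bundle to
new run files.  All randomness flows from a single seed and boosters run
single-threaded, so reruns with the same config are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import curve_io, dataset, evaluation, model as model_mod, normalization
from .errors import PipelineError, TacallError
from .evaluation import EvalReport
from .model import (
    DEFAULT_CLASSIFIER_PARAMS,
    DEFAULT_REGRESSOR_PARAMS,
    HyperParams,
    SMALL_GRID,
    TwoStageModel,
)

__all__ = ["RunConfig", "run_train_eval", "run_predict"]

log = logging.getLogger("tacall")


@dataclass
class RunConfig:
    """Paths and knobs for a full train-and-evaluate run."""

    traces_path: str | Path
    labels_path: str | Path
    model_dir: str | Path
    out_dir: str | Path
    train_fraction: float = 0.8
    folds: int = 5
    seed: int = 0
    cycles: int = 40
    tune: bool = False
    grid: dict | None = None
    classifier_params: HyperParams = DEFAULT_CLASSIFIER_PARAMS
    regressor_params: HyperParams = DEFAULT_REGRESSOR_PARAMS
    no_amp_ct: float = 40.0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise TacallError("train_fraction must lie strictly in (0, 1)")
        if self.folds < 2:
            raise TacallError("folds must be >= 2")


def _stage(stage: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage, str(exc)) from exc
            return False

    return _Ctx()


def run_train_eval(config: RunConfig) -> EvalReport:
    """Normalize → assemble → split → (tune) → fit → predict → evaluate.

    Writes the model bundle to ``config.model_dir`` and ``calls.csv`` plus
    ``report.json`` to ``config.out_dir``; returns the held-out EvalReport.
    Any stage failure raises :class:`PipelineError` naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("io"):
        traces = curve_io.read_curves(config.traces_path, expected_cycles=config.cycles)
        labels = curve_io.read_labels(config.labels_path, max_ct=float(config.cycles))
        log.info("read %d traces and %d labels", len(traces), len(labels))

    with _stage("normalize"):
        normalized = normalization.normalize_batch(traces)

    with _stage("assemble"):
        ds = dataset.assemble(normalized, labels)

    with _stage("split"):
        train, test = dataset.split(ds, config.train_fraction, seed=config.seed)
        log.info("split: %d train / %d test reactions", train.n, test.n)

    cls_params, reg_params = config.classifier_params, config.regressor_params
    if config.tune:
        with _stage("tune"):
            grid = config.grid if config.grid is not None else SMALL_GRID
            cls_params, reg_params = model_mod.tune(
                train, grid, k=config.folds, seed=config.seed
            )
            log.info("tuned classifier=%s regressor=%s", cls_params, reg_params)

    with _stage("fit"):
        fitted = model_mod.fit(train, cls_params, reg_params, seed=config.seed)
        log.info(
            "fitted on %d rows (%d amplified for the Ct regressor)",
            fitted.metadata["n_train"], fitted.metadata["n_train_amplified"],
        )
        model_mod.save_model(fitted, config.model_dir)

    with _stage("predict"):
        calls = model_mod.predict(fitted, test)
        curve_io.write_calls(calls, out_dir / "calls.csv")
        n_flagged = sum(c.flagged for c in calls)
        log.info("%d of %d held-out calls flagged for manual review",
                 n_flagged, len(calls))

    with _stage("evaluate"):
        report = evaluation.evaluate(calls, test.labels(), no_amp_ct=config.no_amp_ct)
        payload = report.to_dict()
        payload["config"] = {
            "train_fraction": config.train_fraction,
            "folds": config.folds,
            "seed": config.seed,
            "tuned": config.tune,
            "classifier_params": fitted.metadata["classifier_params"],
            "regressor_params": fitted.metadata["regressor_params"],
            "n_train": train.n,
            "n_test": test.n,
        }
        (out_dir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    return report


def run_predict(
    model_dir: str | Path,
    traces_path: str | Path,
    out_path: str | Path,
) -> list[curve_io.CallRecord]:
    """Apply a persisted model bundle to a trace file; write and return calls."""
    with _stage("io"):
        fitted = model_mod.load_model(model_dir)
        traces = curve_io.read_curves(traces_path, expected_cycles=fitted.cycles)

    with _stage("normalize"):
        normalized = normalization.normalize_batch(traces)

    with _stage("predict"):
        X = np.vstack([t.values for t in normalized])
        ids = [t.reaction_id for t in normalized]
        calls = model_mod.predict(fitted, X, ids=ids)
        curve_io.write_calls(calls, out_path)
        n_flagged = sum(c.flagged for c in calls)
        log.info("%d of %d calls flagged for manual review", n_flagged, len(calls))
    return calls
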