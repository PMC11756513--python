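"""Two-stage gradient-boosted calling pipeline.

Stage one is a gradient-boosted classifier (XGBoost, binary logistic loss)
that maps the 40 normalized fluorescence values to an amplification
probability; a call is positive only when the probability is strictly greater
than 0.5.  Stage two, applied conditionally on a positive call, is a
gradient-boosted regressor (squared-error loss) trained only on reactions the
gold standard marks amplified, predicting the Ct.  Probabilities in the
closed interval [0.1, 0.9] are flagged for manual review.

Hyperparameters can be tuned by grid search with k-fold cross-validation
(classifier selected on log-loss, regressor on MAE); the boosting-round count
is chosen by early stopping inside the cross-validation rather than being a
grid axis.  The published optima for the original large TAC corpus ship as
named presets for provenance, but tuning on a given dataset is expected to
select different points.
"""

from __future__ import annotations

import json
import itertools
from dataclasses import dataclass, asdict, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import xgboost as xgb

from .curve_io import CallRecord, make_call
from .dataset import ReactionDataset, amplified_subset
from .errors import ModelError

__all__ = [
    "HyperParams",
    "TwoStageModel",
    "FULL_GRID",
    "SMALL_GRID",
    "CLASSIFIER_PRESET",
    "REGRESSOR_PRESET",
    "DEFAULT_CLASSIFIER_PARAMS",
    "DEFAULT_REGRESSOR_PARAMS",
    "expand_grid",
    "tune",
    "fit",
    "predict",
    "save_model",
    "load_model",
]

MAX_ROUNDS = 500
EARLY_STOPPING_PATIENCE = 20


@dataclass(frozen=True)
class HyperParams:
    """One XGBoost configuration; ``n_rounds=None`` means early-stopped."""

    eta: float = 0.3
    max_depth: int = 6
    min_child_weight: float = 1.0
    subsample: float = 1.0
    gamma: float = 0.0
    colsample_bytree: float = 1.0
    n_rounds: int | None = None

    def booster_params(self, objective: str, seed: int) -> dict:
        return {
            "eta": self.eta,
            "max_depth": self.max_depth,
            "min_child_weight": self.min_child_weight,
            "subsample": self.subsample,
            "gamma": self.gamma,
            "colsample_bytree": self.colsample_bytree,
            "objective": objective,
            "seed": seed,
            "nthread": 1,
        }


# Full tuning grid considered for both model stages (4*9*3*3*3*3 = 2916 settings).
FULL_GRID: dict[str, list] = {
    "eta": [0.1, 0.3, 0.5, 0.7],
    "max_depth": list(range(10, 19)),
    "min_child_weight": [1, 5, 10],
    "subsample": [0.5, 0.7, 1.0],
    "gamma": [0.0, 0.1, 0.2],
    "colsample_bytree": [0.5, 0.7, 1.0],
}

# A practical 16-point grid for desk-scale datasets.
SMALL_GRID: dict[str, list] = {
    "eta": [0.1, 0.3],
    "max_depth": [4, 8],
    "min_child_weight": [1, 5],
    "subsample": [0.7, 1.0],
    "gamma": [0.0],
    "colsample_bytree": [1.0],
}

# Published optima for the original 132k-reaction TAC training corpus;
# provenance presets, not defaults for new data.
CLASSIFIER_PRESET = HyperParams(
    eta=0.5, max_depth=13, min_child_weight=1, subsample=0.7,
    gamma=0.1, colsample_bytree=0.7,
)
REGRESSOR_PRESET = HyperParams(
    eta=0.1, max_depth=16, min_child_weight=10, subsample=1.0,
    gamma=0.2, colsample_bytree=1.0,
)

# Untuned defaults: moderate depth and learning rate, rounds by early stop.
DEFAULT_CLASSIFIER_PARAMS = HyperParams(eta=0.3, max_depth=6)
DEFAULT_REGRESSOR_PARAMS = HyperParams(eta=0.1, max_depth=6, min_child_weight=5)


def expand_grid(grid: Mapping[str, Sequence]) -> list[HyperParams]:
    """Cartesian product of a ``{param: values}`` grid into HyperParams."""
    keys = list(grid)
    points = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        points.append(HyperParams(**dict(zip(keys, combo))))
    return points


@dataclass
class TwoStageModel:
    """Fitted classifier + conditional Ct regressor with the calling rules."""

    classifier: xgb.Booster
    regressor: xgb.Booster
    cycles: int
    threshold: float = 0.5
    flag_interval: tuple[float, float] = (0.1, 0.9)
    metadata: dict = field(default_factory=dict)


def _cv_select(
    X: np.ndarray,
    y: np.ndarray,
    params: HyperParams,
    objective: str,
    metric: str,
    k: int,
    seed: int,
) -> tuple[float, int]:
    """Mean CV loss and early-stopped round count for one grid point."""
    dtrain = xgb.DMatrix(X, label=y)
    booster_params = params.booster_params(objective, seed)
    booster_params["eval_metric"] = metric
    stratified = objective == "binary:logistic"
    res = xgb.cv(
        booster_params,
        dtrain,
        num_boost_round=params.n_rounds or MAX_ROUNDS,
        nfold=k,
        stratified=stratified,
        seed=seed,
        early_stopping_rounds=None if params.n_rounds else EARLY_STOPPING_PATIENCE,
        shuffle=True,
    )
    col = f"test-{metric}-mean"
    if params.n_rounds:
        # fixed round count: score the grid point exactly as specified
        return float(res[col].iloc[-1]), params.n_rounds
    best_iter = int(res[col].idxmin())
    return float(res[col].iloc[best_iter]), best_iter + 1


def tune(
    train: ReactionDataset,
    classifier_grid: Mapping[str, Sequence] | Sequence[HyperParams] = SMALL_GRID,
    regressor_grid: Mapping[str, Sequence] | Sequence[HyperParams] | None = None,
    k: int = 5,
    seed: int = 0,
) -> tuple[HyperParams, HyperParams]:
    """Grid-search both stages with k-fold cross-validation.

    The classifier is selected on mean CV log-loss over all training rows;
    the regressor on mean CV MAE over the gold-amplified subset only.  Each
    winning point carries the early-stopped round count.  Deterministic for
    fixed data, grid, and seed.
    """
    if k < 2:
        raise ModelError("cross-validation requires k >= 2 folds")
    cls_points = list(classifier_grid) if not isinstance(classifier_grid, Mapping) \
        else expand_grid(classifier_grid)
    if regressor_grid is None:
        reg_points = cls_points
    else:
        reg_points = list(regressor_grid) if not isinstance(regressor_grid, Mapping) \
            else expand_grid(regressor_grid)
    if not cls_points or not reg_points:
        raise ModelError("tuning grid must be non-empty")

    y = train.amplified.astype(int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if min(n_pos, n_neg) < k:
        raise ModelError(
            f"cannot form {k} stratified folds with class counts "
            f"pos={n_pos}, neg={n_neg}"
        )

    best_cls, best_cls_loss = None, np.inf
    for p in cls_points:
        loss, rounds = _cv_select(
            train.features, y, p, "binary:logistic", "logloss", k, seed
        )
        if loss < best_cls_loss:
            best_cls_loss, best_cls = loss, replace(p, n_rounds=rounds)

    amp = amplified_subset(train)
    if amp.n < k:
        raise ModelError(
            f"cannot cross-validate the Ct regressor: only {amp.n} amplified rows"
        )
    best_reg, best_reg_loss = None, np.inf
    for p in reg_points:
        loss, rounds = _cv_select(
            amp.features, amp.ct, p, "reg:squarederror", "mae", k, seed
        )
        if loss < best_reg_loss:
            best_reg_loss, best_reg = loss, replace(p, n_rounds=rounds)

    return best_cls, best_reg


def _select_rounds(
    X: np.ndarray, y: np.ndarray, params: HyperParams,
    objective: str, metric: str, seed: int,
) -> int:
    _, rounds = _cv_select(X, y, params, objective, metric, k=5, seed=seed)
    return rounds


def fit(
    train: ReactionDataset,
    classifier_params: HyperParams = DEFAULT_CLASSIFIER_PARAMS,
    regressor_params: HyperParams = DEFAULT_REGRESSOR_PARAMS,
    seed: int = 0,
) -> TwoStageModel:
    """Train the classifier on all rows and the regressor on amplified rows.

    When a stage's ``n_rounds`` is unset, the round count is chosen by
    early-stopped 5-fold cross-validation on that stage's own training rows,
    then the final booster is refit on all of them.
    """
    if train.n == 0:
        raise ModelError("training set is empty")
    y = train.amplified.astype(int)
    amp = amplified_subset(train)
    if amp.n == 0:
        raise ModelError("no gold-amplified reactions: Ct regressor untrainable")

    cls_rounds = classifier_params.n_rounds or _select_rounds(
        train.features, y, classifier_params, "binary:logistic", "logloss", seed
    )
    reg_rounds = regressor_params.n_rounds or _select_rounds(
        amp.features, amp.ct, regressor_params, "reg:squarederror", "mae", seed
    )

    dtrain = xgb.DMatrix(train.features, label=y)
    classifier = xgb.train(
        classifier_params.booster_params("binary:logistic", seed),
        dtrain,
        num_boost_round=cls_rounds,
    )
    damp = xgb.DMatrix(amp.features, label=amp.ct)
    regressor = xgb.train(
        regressor_params.booster_params("reg:squarederror", seed),
        damp,
        num_boost_round=reg_rounds,
    )
    return TwoStageModel(
        classifier=classifier,
        regressor=regressor,
        cycles=train.cycles,
        metadata={
            "seed": seed,
            "n_train": train.n,
            "n_train_amplified": amp.n,
            "classifier_params": asdict(replace(classifier_params, n_rounds=cls_rounds)),
            "regressor_params": asdict(replace(regressor_params, n_rounds=reg_rounds)),
            "version": 1,
        },
    )


def predict(
    model: TwoStageModel,
    features: ReactionDataset | np.ndarray,
    ids: Sequence[str] | None = None,
) -> list[CallRecord]:
    """Apply the two-stage model, yielding one :class:`CallRecord` per row.

    The regressor runs only on rows the classifier calls amplified, so a Ct
    is emitted exactly for positive calls (probability strictly above the
    threshold); probabilities inside the flag interval are marked for review.
    """
    if isinstance(features, ReactionDataset):
        X = features.features
        ids = features.ids
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if ids is None:
            ids = [f"r{i + 1}" for i in range(X.shape[0])]
    if X.shape[1] != model.cycles:
        raise ModelError(
            f"model expects {model.cycles} cycles per reaction, got {X.shape[1]}"
        )
    if len(ids) != X.shape[0]:
        raise ModelError("ids must align with feature rows")

    probs = model.classifier.predict(xgb.DMatrix(X))
    positive = probs > model.threshold
    cts = np.full(X.shape[0], np.nan)
    if positive.any():
        cts[positive] = model.regressor.predict(xgb.DMatrix(X[positive]))
    return [
        make_call(
            rid,
            float(p),
            float(ct) if pos else None,
            threshold=model.threshold,
            flag_interval=model.flag_interval,
        )
        for rid, p, pos, ct in zip(ids, probs, positive, cts)
    ]


def save_model(model: TwoStageModel, directory: str | Path) -> Path:
    """Persist the bundle: two booster JSON files plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.classifier.save_model(directory / "classifier.json")
    model.regressor.save_model(directory / "regressor.json")
    manifest = {
        "cycles": model.cycles,
        "threshold": model.threshold,
        "flag_interval": list(model.flag_interval),
        "metadata": model.metadata,
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return directory


def load_model(directory: str | Path) -> TwoStageModel:
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise ModelError(f"no model manifest at {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    classifier = xgb.Booster()
    classifier.load_model(directory / "classifier.json")
    regressor = xgb.Booster()
    regressor.load_model(directory / "regressor.json")
    return TwoStageModel(
        classifier=classifier,
        regressor=regressor,
        cycles=int(manifest["cycles"]),
        threshold=float(manifest["threshold"]),
        flag_interval=tuple(manifest["flag_interval"]),
        metadata=manifest.get("metadata", {}),
    )
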