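"""The five regressor families under one train/predict contract.

Families: random forest (rf), RBF-kernel support vector regression (svr),
gradient-boosted trees (xgb), a two-layer single-timestep LSTM network
(lstm) and a feed-forward network (dnn). All are driven through
:func:`train` / :func:`predict` with a :class:`ModelSpec`, so the
benchmark harness never special-cases a family.

The consensus ensemble averages, without weights, the predictions of two
models of the same family trained on the two standalone fingerprints
(MACCS and ECFP) — the baseline the conjoint representation is compared
against.

Defaults: SVR uses an RBF kernel with C = 5 and gamma = 0.015 (the tuned
values of the original benchmarking protocol); the neural families use
Adam at learning rate 0.001. Tree-model defaults (300 trees / 300
boosting rounds, depth 6) are this package's own choices.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

from . import _nn

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "ConsensusModel",
    "PredictionSet",
    "DEFAULT_HYPERPARAMS",
    "train",
    "predict",
    "consensus_predict",
    "train_consensus",
    "build_dnn",
    "build_lstm",
    "model_capacity",
    "save_model",
    "load_model",
]

FAMILIES = ("rf", "svr", "xgb", "lstm", "dnn")
REPRESENTATIONS = ("maccs", "ecfp", "conjoint", "consensus")

DEFAULT_HYPERPARAMS: dict[str, dict[str, Any]] = {
    "rf": {"n_estimators": 300, "max_depth": None, "min_samples_leaf": 1},
    "svr": {"kernel": "rbf", "C": 5.0, "gamma": 0.015, "epsilon": 0.1},
    "xgb": {"n_estimators": 300, "max_depth": 6, "learning_rate": 0.1},
    "dnn": {
        "width": 100,
        "activation": "relu",
        "dropout": 0.2,
        "epochs": 100,
        "batch_size": 32,
        "learning_rate": 0.001,
    },
    "lstm": {
        "hidden2": 64,
        "dense_units": 64,
        "dense_activation": "relu",
        "epochs": 60,
        "batch_size": 32,
        "learning_rate": 0.001,
    },
}


@dataclass(frozen=True)
class ModelSpec:
    """Algorithm family + hyperparameters + input representation + seed."""

    family: str
    representation: str = "conjoint"
    hyperparams: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"unknown representation {self.representation!r}")
        unknown = set(self.hyperparams) - set(DEFAULT_HYPERPARAMS[self.family])
        if unknown:
            raise ValueError(
                f"hyperparameters {sorted(unknown)} are not valid for family "
                f"{self.family!r} (valid: {sorted(DEFAULT_HYPERPARAMS[self.family])})"
            )

    def resolved(self) -> dict[str, Any]:
        return {**DEFAULT_HYPERPARAMS[self.family], **self.hyperparams}


@dataclass
class TrainedModel:
    """A fitted model; ``predict`` is deterministic once fitted."""

    spec: ModelSpec
    estimator: Any
    n_features: int
    loss_history: list[tuple[float, float | None]] | None = None


@dataclass
class ConsensusModel:
    """Two same-family models, one per standalone fingerprint."""

    member_a: TrainedModel  # MACCS representation
    member_b: TrainedModel  # ECFP representation

    def __post_init__(self) -> None:
        if self.member_a.spec.family != self.member_b.spec.family:
            raise ValueError("consensus members must share the model family")


@dataclass
class PredictionSet:
    """Aligned true/predicted values for a set of records."""

    ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true, dtype=float).ravel()
        self.y_pred = np.asarray(self.y_pred, dtype=float).ravel()
        if not (len(self.ids) == len(self.y_true) == len(self.y_pred)):
            raise ValueError("ids, y_true and y_pred must have equal lengths")

    def __len__(self) -> int:
        return len(self.ids)


def build_dnn(input_len: int, hyperparams: dict[str, Any] | None = None, seed: int = 0) -> _nn.NeuralNet:
    """Feed-forward net: input -> hidden(width, activation, dropout) -> scalar.

    The hidden width, activation and dropout rate are the searched
    hyperparameters; training uses Adam at learning rate 0.001.
    """
    hp = {**DEFAULT_HYPERPARAMS["dnn"], **(hyperparams or {})}
    if not 0.0 <= hp["dropout"] <= 0.6:
        raise ValueError("dropout must lie in [0, 0.6]")
    layers = [
        _nn.dense(hp["width"], hp["activation"]),
        _nn.dropout(hp["dropout"]),
        _nn.dense(1, "linear"),
    ]
    return _nn.NeuralNet(input_len, layers, seed=seed)


def build_lstm(input_len: int, hyperparams: dict[str, Any] | None = None, seed: int = 0) -> _nn.NeuralNet:
    """Two LSTM layers, one dense layer, one scalar output layer.

    The whole fingerprint is presented as a single timestep and the first
    LSTM layer's output dimension equals the input dimension; the second
    LSTM and dense widths are package defaults (64 each).
    """
    if input_len <= 0:
        raise ValueError("input_len must be positive")
    hp = {**DEFAULT_HYPERPARAMS["lstm"], **(hyperparams or {})}
    layers = [
        _nn.lstm(input_len),
        _nn.lstm(hp["hidden2"]),
        _nn.dense(hp["dense_units"], hp["dense_activation"]),
        _nn.dense(1, "linear"),
    ]
    return _nn.NeuralNet(input_len, layers, seed=seed)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]} entries")
    if not np.isfinite(y).all():
        raise ValueError("targets contain non-finite values")
    return X, y


def train(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> TrainedModel:
    """Fit one model; all stochastic elements are driven by ``spec.seed``.

    For the neural families a per-epoch (train, validation) loss history
    is recorded; pass ``X_val``/``y_val`` to populate the validation side.
    """
    X, y = _check_xy(X, y)
    hp = spec.resolved()
    loss_history = None
    if spec.family == "rf":
        est = RandomForestRegressor(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"],
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=spec.seed,
            n_jobs=1,
        ).fit(X, y)
    elif spec.family == "svr":
        est = SVR(kernel=hp["kernel"], C=hp["C"], gamma=hp["gamma"], epsilon=hp["epsilon"]).fit(X, y)
    elif spec.family == "xgb":
        est = XGBRegressor(
            n_estimators=hp["n_estimators"],
            max_depth=hp["max_depth"],
            learning_rate=hp["learning_rate"],
            random_state=spec.seed,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        ).fit(X, y)
    else:
        builder = build_dnn if spec.family == "dnn" else build_lstm
        est = builder(X.shape[1], spec.hyperparams, seed=spec.seed)
        validation = None
        if X_val is not None and y_val is not None:
            validation = _check_xy(X_val, y_val)
        est.fit(
            X,
            y,
            epochs=hp["epochs"],
            batch_size=hp["batch_size"],
            learning_rate=hp["learning_rate"],
            validation=validation,
        )
        loss_history = list(est.loss_history)
    return TrainedModel(spec=spec, estimator=est, n_features=X.shape[1], loss_history=loss_history)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """One finite prediction per row of ``X``."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"X must have {model.n_features} columns (got shape {X.shape})"
        )
    if X.shape[0] == 0:
        return np.empty(0)
    return np.asarray(model.estimator.predict(X), dtype=float).ravel()


def train_consensus(
    family: str,
    X_maccs: np.ndarray,
    X_ecfp: np.ndarray,
    y: np.ndarray,
    hyperparams: dict[str, Any] | None = None,
    seed: int = 0,
) -> ConsensusModel:
    """Train the two standalone-fingerprint members on identical rows."""
    if X_maccs.shape[0] != X_ecfp.shape[0]:
        raise ValueError("member matrices must be row-aligned")
    spec_a = ModelSpec(family=family, representation="maccs", hyperparams=hyperparams or {}, seed=seed)
    spec_b = replace(spec_a, representation="ecfp")
    return ConsensusModel(
        member_a=train(spec_a, X_maccs, y),
        member_b=train(spec_b, X_ecfp, y),
    )


def consensus_predict(cm: ConsensusModel, X_maccs: np.ndarray, X_ecfp: np.ndarray) -> np.ndarray:
    """Unweighted element-wise mean of the two members' predictions."""
    if X_maccs.shape[0] != X_ecfp.shape[0]:
        raise ValueError("member matrices must have the same row count")
    a = predict(cm.member_a, X_maccs)
    b = predict(cm.member_b, X_ecfp)
    return (a + b) / 2.0


def model_capacity(family: str, hyperparams: dict[str, Any]) -> float:
    """Rough parameter-count proxy used to break grid-search ties.

    Smaller capacity wins ties, biasing the search toward the simpler
    model. The proxy need only order candidates of one family sensibly.
    """
    hp = {**DEFAULT_HYPERPARAMS[family], **hyperparams}
    if family == "rf":
        depth = hp["max_depth"] if hp["max_depth"] is not None else 30
        return hp["n_estimators"] * 2.0**min(depth, 30)
    if family == "xgb":
        return hp["n_estimators"] * 2.0 ** hp["max_depth"]
    if family == "svr":
        return float(hp["C"])
    if family == "dnn":
        return float(hp["width"])
    return float(hp["hidden2"]) + float(hp["dense_units"])


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_BUNDLE_VERSION = 1


def save_model(model: TrainedModel, directory: str | Path) -> Path:
    """Save a versioned bundle: spec as JSON + fitted state as pickle."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "spec.json").write_text(
        json.dumps(
            {
                "bundle_version": _BUNDLE_VERSION,
                "family": model.spec.family,
                "representation": model.spec.representation,
                "hyperparams": model.spec.hyperparams,
                "seed": model.spec.seed,
                "n_features": model.n_features,
            },
            indent=2,
        )
    )
    with (directory / "estimator.pkl").open("wb") as fh:
        pickle.dump({"estimator": model.estimator, "loss_history": model.loss_history}, fh)
    return directory


def load_model(directory: str | Path) -> TrainedModel:
    directory = Path(directory)
    meta = json.loads((directory / "spec.json").read_text())
    if meta.get("bundle_version") != _BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {meta.get('bundle_version')}")
    with (directory / "estimator.pkl").open("rb") as fh:
        state = pickle.load(fh)
    spec = ModelSpec(
        family=meta["family"],
        representation=meta["representation"],
        hyperparams=meta["hyperparams"],
        seed=meta["seed"],
    )
    return TrainedModel(
        spec=spec,
        estimator=state["estimator"],
        n_features=meta["n_features"],
        loss_history=state["loss_history"],
    )
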