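"""Point-classification models.

A model consumes one feature row per point — the sequence of distances
to its k nearest neighbors — and scores the point as clustered or not
(or, for the 3-class variant, as round-cluster / fiber / background).
Five named presets cover the published topologies:

=======  =======  =========  =============================================
name     input k  classes    architecture (after the input layer)
=======  =======  =========  =============================================
XPILJZ   100      2          two fully connected layers -> softmax
07VEJJ   100      2          conv/pool/dropout x2, two stacked LSTMs,
                             dropout, dense -> softmax (12 layers total)
87B144   1000     2          as 07VEJJ with a 1000-neighbor input window
GAXJPR   1000     2          as XPILJZ with a 1000-neighbor window,
                             intended for 3D distance features
3TXKFS   1000     3          one fully connected layer -> 3-way softmax
=======  =======  =========  =============================================

Layer counts include the input layer, matching the usual
sequential-stack bookkeeping.  Exact widths, kernel sizes and dropout
rates are configurable defaults, not canonical values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    precision_recall_fscore_support,
)
from sklearn.model_selection import StratifiedKFold

from . import nn
from .features import FeatureMatrix, LabeledPool

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "Metrics",
    "PointLabels",
    "TrainConfig",
    "model_preset",
    "train",
    "evaluate",
    "cross_validate",
    "classify",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture description: an ordered stack of layer descriptors.

    ``layers`` excludes the input layer; ``n_layers`` counts it back in.
    The final descriptor must be ``output-softmax``.
    """

    name: str
    input_k: int
    n_classes: int
    layers: tuple

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not self.layers or self.layers[-1]["kind"] != "output-softmax":
            raise ValueError("the last layer must be 'output-softmax'")

    @property
    def n_layers(self) -> int:
        """Total layer count, input layer included."""
        return len(self.layers) + 1

    @property
    def needs_sequence_input(self) -> bool:
        return any(l["kind"] in ("conv-1d", "max-pool", "lstm") for l in self.layers)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_k": self.input_k,
            "n_classes": self.n_classes,
            "layers": list(self.layers),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            name=d["name"],
            input_k=d["input_k"],
            n_classes=d["n_classes"],
            layers=tuple(d["layers"]),
        )


def _dense_stack(name: str, input_k: int, hidden: tuple[int, ...], n_classes: int) -> ModelSpec:
    layers = tuple(
        {"kind": "dense", "units": u, "activation": "relu"} for u in hidden
    ) + ({"kind": "output-softmax"},)
    return ModelSpec(name=name, input_k=input_k, n_classes=n_classes, layers=layers)


def _recurrent_stack(name: str, input_k: int) -> ModelSpec:
    layers = (
        {"kind": "conv-1d", "filters": 32, "width": 5, "activation": "relu"},
        {"kind": "max-pool", "size": 2},
        {"kind": "dropout", "rate": 0.25},
        {"kind": "conv-1d", "filters": 64, "width": 5, "activation": "relu"},
        {"kind": "max-pool", "size": 2},
        {"kind": "dropout", "rate": 0.25},
        {"kind": "lstm", "units": 64, "return_sequences": True},
        {"kind": "lstm", "units": 32, "return_sequences": False},
        {"kind": "dropout", "rate": 0.25},
        {"kind": "dense", "units": 32, "activation": "relu"},
        {"kind": "output-softmax"},
    )
    return ModelSpec(name=name, input_k=input_k, n_classes=2, layers=layers)


_PRESETS = {
    "XPILJZ": lambda: _dense_stack("XPILJZ", 100, (128, 64), 2),
    "07VEJJ": lambda: _recurrent_stack("07VEJJ", 100),
    "87B144": lambda: _recurrent_stack("87B144", 1000),
    "GAXJPR": lambda: _dense_stack("GAXJPR", 1000, (128, 64), 2),
    "3TXKFS": lambda: _dense_stack("3TXKFS", 1000, (128,), 3),
}
PRESET_NAMES = tuple(_PRESETS)


def model_preset(name: str) -> ModelSpec:
    """Return a named preset architecture."""
    try:
        return _PRESETS[name]()
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        ) from None


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults: Adam 1e-3, batch 256,
    up to 50 epochs, early stopping patience 5 on validation accuracy)."""

    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 1e-3
    patience: int = 5
    seed: int = 0
    verbose: bool = False


@dataclass
class TrainedModel:
    """A ModelSpec plus learned parameters and training provenance."""

    spec: ModelSpec
    network: nn.Sequential
    history: dict
    training_meta: dict = field(default_factory=dict)

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        x = _prepare_input(self.spec, features)
        return self.network.predict_proba(x)

    # -- persistence --------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", **self.network.get_params())
        sidecar = {
            "spec": self.spec.to_dict(),
            "training_meta": self.training_meta,
            "history": self.history,
        }
        (directory / "model.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        sidecar = json.loads((directory / "model.json").read_text())
        spec = ModelSpec.from_dict(sidecar["spec"])
        net = _build_network(spec, seed=0)
        with np.load(directory / "weights.npz") as data:
            net.set_params({k: data[k] for k in data.files})
        return cls(
            spec=spec,
            network=net,
            history=sidecar.get("history", {}),
            training_meta=sidecar.get("training_meta", {}),
        )


@dataclass
class Metrics:
    """Evaluation summary: fractions in [0, 1] plus the confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion.tolist(),
        }


@dataclass
class PointLabels:
    """Per-point class scores and hard labels for one field."""

    scores: np.ndarray
    label: np.ndarray

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.label):
            raise ValueError("scores and labels must align")


def _build_network(spec: ModelSpec, seed: int) -> nn.Sequential:
    layers: list[nn.Layer] = []
    for desc in spec.layers:
        kind = desc["kind"]
        if kind == "dense":
            layers.append(nn.Dense(desc["units"], desc.get("activation", "relu")))
        elif kind == "conv-1d":
            layers.append(
                nn.Conv1D(desc["filters"], desc["width"], desc.get("activation", "relu"))
            )
        elif kind == "max-pool":
            layers.append(nn.MaxPool1D(desc.get("size", 2)))
        elif kind == "dropout":
            layers.append(nn.Dropout(desc.get("rate", 0.25)))
        elif kind == "lstm":
            layers.append(nn.LSTM(desc["units"], desc.get("return_sequences", False)))
        elif kind == "output-softmax":
            layers.append(nn.Dense(spec.n_classes, activation=None))
        else:
            raise ValueError(f"unknown layer kind {kind!r}")
    input_shape = (spec.input_k, 1) if spec.needs_sequence_input else (spec.input_k,)
    return nn.Sequential(layers, input_shape=input_shape, seed=seed)


def _prepare_input(spec: ModelSpec, features: np.ndarray) -> np.ndarray:
    features = np.asarray(features)
    if features.dtype.kind != "f":
        features = features.astype(float)
    if features.ndim != 2 or features.shape[1] != spec.input_k:
        raise ValueError(
            f"feature width {features.shape[1] if features.ndim == 2 else '?'} "
            f"does not match model input_k={spec.input_k}"
        )
    if spec.needs_sequence_input:
        return features[:, :, None]
    return features


def train(
    spec: ModelSpec,
    train_pool: LabeledPool,
    val_pool: LabeledPool,
    config: TrainConfig | None = None,
) -> TrainedModel:
    """Train a network on labelled feature pools.

    Deterministic for a fixed config seed under single-threaded
    execution.  Raises on feature-width or label-arity mismatches before
    any compute, and surfaces divergence (non-finite loss) with the
    offending epoch.
    """
    config = config or TrainConfig()
    for pool in (train_pool, val_pool):
        if pool.k != spec.input_k:
            raise ValueError(
                f"pool feature width {pool.k} != model input_k {spec.input_k}"
            )
        if pool.labels.min() < 0 or pool.labels.max() >= spec.n_classes:
            raise ValueError(
                f"pool labels outside [0, {spec.n_classes - 1}] for {spec.name}"
            )
    net = _build_network(spec, seed=config.seed)
    history = net.fit(
        _prepare_input(spec, train_pool.features),
        train_pool.labels,
        _prepare_input(spec, val_pool.features),
        val_pool.labels,
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        patience=config.patience,
        verbose=config.verbose,
    )
    meta = {
        "seed": config.seed,
        "epochs_run": len(history["loss"]),
        "batch_size": config.batch_size,
        "learning_rate": config.learning_rate,
        "n_train": train_pool.n,
        "n_val": val_pool.n,
    }
    return TrainedModel(spec=spec, network=net, history=history, training_meta=meta)


def evaluate(model: TrainedModel, test_pool: LabeledPool) -> Metrics:
    """Accuracy, macro-averaged precision/recall/F1 and the confusion matrix."""
    if test_pool.n == 0:
        raise ValueError("test pool is empty")
    if test_pool.k != model.spec.input_k:
        raise ValueError(
            f"pool feature width {test_pool.k} != model input_k {model.spec.input_k}"
        )
    scores = model.predict_scores(test_pool.features)
    preds = scores.argmax(axis=1)
    y = test_pool.labels
    labels_range = list(range(model.spec.n_classes))
    precision, recall, f1, _ = precision_recall_fscore_support(
        y, preds, labels=labels_range, average="macro", zero_division=0
    )
    return Metrics(
        accuracy=float(accuracy_score(y, preds)),
        precision=float(precision),
        recall=float(recall),
        f1=float(f1),
        confusion=confusion_matrix(y, preds, labels=labels_range),
    )


def cross_validate(
    spec: ModelSpec,
    pool: LabeledPool,
    n_folds: int = 10,
    seed: int = 0,
    config: TrainConfig | None = None,
) -> tuple[float, float]:
    """Stratified k-fold cross validation; returns (mean, sd) accuracy."""
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if pool.n < n_folds:
        raise ValueError(f"pool of {pool.n} rows cannot form {n_folds} folds")
    config = config or TrainConfig()
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(pool.features, pool.labels)):
        fold_cfg = TrainConfig(
            epochs=config.epochs,
            batch_size=config.batch_size,
            learning_rate=config.learning_rate,
            patience=config.patience,
            seed=config.seed + fold,
            verbose=config.verbose,
        )
        tr_pool = LabeledPool(pool.features[tr], pool.labels[tr], split="train")
        te_pool = LabeledPool(pool.features[te], pool.labels[te], split="test")
        model = train(spec, tr_pool, te_pool, fold_cfg)
        accs.append(evaluate(model, te_pool).accuracy)
    return float(np.mean(accs)), float(np.std(accs))


def classify(
    model: TrainedModel, fm: FeatureMatrix, threshold: float = 0.5
) -> PointLabels:
    """Score every feature row and assign hard labels.

    Binary models threshold the clustered-class score (score >= threshold
    labels the point clustered — a tie goes to the positive class);
    multi-class models take the argmax.  Row order is preserved.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    scores = model.predict_scores(fm.values)
    if model.spec.n_classes == 2:
        label = (scores[:, 1] >= threshold).astype(int)
    else:
        label = scores.argmax(axis=1)
    return PointLabels(scores=scores, label=label)
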