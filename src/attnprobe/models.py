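"""Contact-map classifiers over attention features.

Five tabular classifiers -- logistic regression, decision tree, random
forest, multilayer perceptron, gradient boosting (XGBoost) -- are
trained on balanced token-pair tables, plus a convolutional map-to-map
predictor.  A trained model turns a processed attention stack back into
a predicted contact map: per-pair probabilities mirrored to the lower
triangle, the exclusion band forced to zero, and a 0.5 threshold for
the binary map.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import joblib
import numpy as np

from .attention import AttentionStack
from .cnn import ContactCNN
from .contacts import ContactMap, eligible_pairs
from .errors import (
    AlignmentError,
    ConfigError,
    FeatureError,
    LoadError,
    ShapeError,
    StateError,
    TrainingError,
)
from .features import PairDataset, feature_names

_FORMAT_VERSION = 1


class PredictorKind(str, Enum):
    LOGISTIC = "logistic"
    DECISION_TREE = "decision_tree"
    RANDOM_FOREST = "random_forest"
    MLP = "mlp"
    GRADIENT_BOOSTING = "gradient_boosting"
    CNN = "cnn"


@dataclass(frozen=True)
class PredictorSpec:
    kind: PredictorKind
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "kind", PredictorKind(self.kind))


@dataclass
class TrainedPredictor:
    spec: PredictorSpec
    model: object  # fitted sklearn/xgboost estimator or ContactCNN
    feature_names: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


@dataclass
class PredictedMap:
    """Probability map plus its thresholded binary contact map."""

    n: int
    prob: np.ndarray
    binary: ContactMap
    threshold: float

    def __post_init__(self):
        self.prob = np.asarray(self.prob, dtype=np.float64)
        if self.prob.shape != (self.n, self.n):
            raise ShapeError(f"prob shape {self.prob.shape} != ({self.n}, {self.n})")


def _make_estimator(spec: PredictorSpec):
    hp = dict(spec.hyperparameters)
    kind = spec.kind
    if kind is PredictorKind.LOGISTIC:
        from sklearn.linear_model import LogisticRegression

        return LogisticRegression(max_iter=1000, random_state=spec.seed, **hp)
    if kind is PredictorKind.DECISION_TREE:
        from sklearn.tree import DecisionTreeClassifier

        return DecisionTreeClassifier(random_state=spec.seed, **hp)
    if kind is PredictorKind.RANDOM_FOREST:
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(random_state=spec.seed, n_jobs=1, **hp)
    if kind is PredictorKind.MLP:
        from sklearn.neural_network import MLPClassifier

        hp.setdefault("max_iter", 300)
        return MLPClassifier(random_state=spec.seed, **hp)
    if kind is PredictorKind.GRADIENT_BOOSTING:
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=spec.seed, n_jobs=1, eval_metric="logloss", **hp
        )
    raise ConfigError(f"unknown tabular classifier kind {kind!r}")


def train_tabular(ds: PairDataset, spec: PredictorSpec) -> TrainedPredictor:
    """Fit one of the five tabular classifiers on a balanced pair table."""
    if spec.kind is PredictorKind.CNN:
        raise ConfigError("use train_cnn for the convolutional predictor")
    if len(ds) == 0:
        raise TrainingError("cannot train on an empty dataset")
    if not ds.balanced:
        raise TrainingError("training table must be class-balanced first")
    est = _make_estimator(spec)
    est.fit(ds.features, ds.labels.astype(int))
    prov = {
        "n_samples": len(ds),
        "dataset_hash": ds.content_hash(),
        "hyperparameters": {
            k: repr(v) for k, v in sorted(est.get_params().items())
        },
    }
    return TrainedPredictor(
        spec=spec, model=est, feature_names=list(ds.feature_names), provenance=prov
    )


def predict_pairs(model: TrainedPredictor, features: np.ndarray) -> np.ndarray:
    """Per-sample contact probability from a tabular model."""
    if features.shape[1] != model.n_features:
        raise FeatureError(
            f"feature width {features.shape[1]} != model's {model.n_features}"
        )
    proba = model.model.predict_proba(features)
    classes = list(model.model.classes_)
    return proba[:, classes.index(1)]


def predict_contact_map(
    model: TrainedPredictor,
    stack: AttentionStack,
    window: int,
    threshold: float = 0.5,
) -> PredictedMap:
    """Predicted contact map for one molecule.

    Eligible pairs receive the model probability (mirrored to the lower
    triangle); the exclusion band and diagonal are defined as 0.
    """
    if not stack.processed:
        raise StateError(f"stack {stack.molecule_id} must be processed first")
    n = stack.n
    prob = np.zeros((n, n))
    if model.spec.kind is PredictorKind.CNN:
        net: ContactCNN = model.model
        if stack.n_layers * stack.n_heads != net.n_channels:
            raise FeatureError(
                f"stack has {stack.n_layers * stack.n_heads} channels, "
                f"model expects {net.n_channels}"
            )
        full = net.forward(stack.weights.reshape(-1, n, n))
        ii, jj = eligible_pairs(n, window)
        prob[ii, jj] = full[ii, jj]
        prob[jj, ii] = full[ii, jj]
    else:
        expected = feature_names(stack.n_layers, stack.n_heads)
        if expected != model.feature_names:
            raise FeatureError(
                f"stack feature layout ({stack.n_layers}x{stack.n_heads}) does "
                "not match the model's training layout"
            )
        ii, jj = eligible_pairs(n, window)
        if ii.size:
            feats = stack.weights[:, :, ii, jj].reshape(len(expected), -1).T
            p = predict_pairs(model, feats)
            prob[ii, jj] = p
            prob[jj, ii] = p
    binary = ContactMap(
        n=n,
        matrix=(prob >= threshold).astype(np.int8),
        exclusion_window=window,
        cutoff=None,
    )
    return PredictedMap(n=n, prob=prob, binary=binary, threshold=threshold)


def train_cnn(
    stacks: list[AttentionStack],
    maps: list[ContactMap],
    spec: PredictorSpec,
    window: int = 4,
    max_length: int | None = None,
) -> TrainedPredictor:
    """Train the convolutional map-to-map predictor.

    Molecules are zero-padded to ``max_length`` (default: longest in the
    set); the loss only sees eligible, unpadded pixels.
    """
    if spec.kind is not PredictorKind.CNN:
        raise ConfigError(f"train_cnn requires kind=cnn, got {spec.kind}")
    if len(stacks) != len(maps):
        raise AlignmentError(f"{len(stacks)} stacks but {len(maps)} maps")
    if not stacks:
        raise TrainingError("cannot train on an empty corpus")
    channels = {s.n_layers * s.n_heads for s in stacks}
    if len(channels) != 1:
        raise ShapeError(f"inconsistent channel counts across molecules: {channels}")
    n_channels = channels.pop()
    pad_to = max_length or max(s.n for s in stacks)

    xs, ys, ms = [], [], []
    for stack, cmap in zip(stacks, maps):
        if not stack.processed:
            raise StateError(f"stack {stack.molecule_id} must be processed first")
        if stack.n != cmap.n:
            raise AlignmentError(f"molecule {stack.molecule_id}: length mismatch")
        n = min(stack.n, pad_to)
        x = np.zeros((n_channels, pad_to, pad_to))
        x[:, :n, :n] = stack.weights.reshape(-1, stack.n, stack.n)[:, :n, :n]
        y = np.zeros((pad_to, pad_to))
        y[:n, :n] = cmap.matrix[:n, :n]
        i, j = np.indices((pad_to, pad_to), sparse=True)
        mask = (np.abs(i - j) > window) & (i < n) & (j < n)
        xs.append(x)
        ys.append(y)
        ms.append(mask)

    hp = dict(spec.hyperparameters)
    net = ContactCNN(
        n_channels, hidden=int(hp.pop("hidden", 8)), seed=spec.seed
    )
    curve = net.fit(
        xs, ys, ms,
        epochs=int(hp.pop("epochs", 30)),
        lr=float(hp.pop("lr", 0.02)),
        seed=spec.seed,
    )
    if hp:
        raise ConfigError(f"unknown CNN hyperparameters: {sorted(hp)}")
    h = hashlib.sha256()
    for x in xs:
        h.update(np.ascontiguousarray(x).tobytes())
    prov = {
        "n_molecules": len(stacks),
        "pad_to": pad_to,
        "final_loss": curve[-1],
        "dataset_hash": h.hexdigest(),
    }
    return TrainedPredictor(
        spec=spec,
        model=net,
        feature_names=feature_names(stacks[0].n_layers, stacks[0].n_heads),
        provenance=prov,
    )


def save_model(model: TrainedPredictor, path: str | Path) -> None:
    """Persist a trained predictor (self-describing archive)."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "spec": {
            "kind": model.spec.kind.value,
            "hyperparameters": model.spec.hyperparameters,
            "seed": model.spec.seed,
        },
        "feature_names": model.feature_names,
        "provenance": model.provenance,
        "model": (
            model.model.state_dict()
            if isinstance(model.model, ContactCNN)
            else model.model
        ),
        "is_cnn": isinstance(model.model, ContactCNN),
    }
    joblib.dump(payload, path)


def load_model(path: str | Path) -> TrainedPredictor:
    try:
        payload = joblib.load(path)
    except Exception as exc:
        raise LoadError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(payload, dict) or "format_version" not in payload:
        raise LoadError(f"{path}: not an attnprobe model archive")
    if payload["format_version"] != _FORMAT_VERSION:
        raise LoadError(
            f"{path}: model format version {payload['format_version']} "
            f"!= supported {_FORMAT_VERSION}"
        )
    spec = PredictorSpec(
        kind=payload["spec"]["kind"],
        hyperparameters=payload["spec"]["hyperparameters"],
        seed=payload["spec"]["seed"],
    )
    model = (
        ContactCNN.from_state_dict(payload["model"])
        if payload["is_cnn"]
        else payload["model"]
    )
    return TrainedPredictor(
        spec=spec,
        model=model,
        feature_names=payload["feature_names"],
        provenance=payload["provenance"],
    )
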