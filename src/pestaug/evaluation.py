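"""Desk-scale classifier harness for measuring augmentation contributions.

The evaluation protocol mirrors transfer-learning practice for pest
classification: a frozen convolutional feature extractor (the "backbone")
feeds a trainable two-layer dense head — 512 rectified-linear units with
dropout 0.5, then a softmax layer over the classes — optimized with Adam on
categorical cross-entropy, recording train and validation accuracy every
epoch.  The bundled ``tiny`` backbone is a seeded random-filter convolutional
stack that runs on one CPU with no deep-learning framework; the named
ImageNet backbones (vgg16, vgg19, resnet50) attach only when the optional
tensorflow dependency is installed.

Accuracy is the fraction of correct predictions; an augmentation strategy's
contribution is its validation-accuracy improvement relative to the
no-augmentation baseline, as a percent of the baseline.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import ImageRecord, LabeledDataset, ValidationError
from .dataset_io import resize

__all__ = [
    "HeadSpec", "TrainConfig", "EvalResult", "CapabilityError", "LeakageError",
    "accuracy", "contribution_percent", "build_classifier", "train_and_evaluate",
]


class CapabilityError(RuntimeError):
    """A requested backbone needs an optional dependency that is not installed."""


class LeakageError(ValueError):
    """Training data contains (a derivative of) a validation sample."""


@dataclass(frozen=True)
class HeadSpec:
    """The modified fully connected head: dense-512-ReLU-dropout, dense-softmax."""

    output_units: int
    hidden_units: int = 512
    hidden_activation: str = "relu"
    dropout: float = 0.5
    output_activation: str = "softmax"

    def __post_init__(self) -> None:
        if self.output_units < 2:
            raise ValidationError("head needs >= 2 output units")


_BACKBONE_SIDES = {"tiny": 32, "vgg16": 224, "vgg19": 224, "resnet50": 124}


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: Adam, lr 0.001, batch 32, cross-entropy, val every epoch."""

    epochs: int = 100
    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 32
    dropout_range: tuple[float, float] = (0.3, 0.5)
    loss: str = "categorical_crossentropy"
    validation_frequency: int = 1
    backbone: str = "tiny"
    input_side: int | None = None
    seed: int = 0
    unfreeze_last_n_blocks: int = 0
    weight_decay: float = 1e-3

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValidationError("epochs, batch size and learning rate must be positive")
        if self.backbone not in _BACKBONE_SIDES:
            raise ValidationError(f"unknown backbone {self.backbone!r}")

    @property
    def side(self) -> int:
        return self.input_side if self.input_side else _BACKBONE_SIDES[self.backbone]


@dataclass
class EvalResult:
    """Per-epoch accuracy curves plus the summary validation accuracy."""

    train_curve: list[float]
    val_curve: list[float]
    final_val_accuracy: float
    config: TrainConfig

    def to_json(self) -> str:
        payload = {
            "train_curve": self.train_curve,
            "val_curve": self.val_curve,
            "final_val_accuracy": self.final_val_accuracy,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.config.__dict__.items()},
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Metrics

def accuracy(predictions: Sequence[str], truth: Sequence[str]) -> float:
    """Fraction of positionwise matches: correct predictions / total predictions."""
    if len(predictions) == 0 or len(predictions) != len(truth):
        raise ValidationError("predictions and truth must be equal-length and non-empty")
    correct = sum(p == t for p, t in zip(predictions, truth))
    return correct / len(predictions)


def contribution_percent(augmented_accuracy: float, baseline_accuracy: float) -> float:
    """Relative improvement over baseline, truncated (not rounded) to 2 decimals.

    ``100 * (augmented - baseline) / baseline``, truncated toward zero; e.g.
    (82.182, 71.123) -> 15.54 and (76.713, 72.552) -> 5.73.
    """
    if baseline_accuracy <= 0:
        raise ValidationError("baseline accuracy must be positive")
    raw = 100.0 * (augmented_accuracy - baseline_accuracy) / baseline_accuracy
    return math.trunc(raw * 100.0) / 100.0


# ---------------------------------------------------------------------------
# Tiny backbone: frozen random convolutional features + trainable dense head

def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h - h % 2, w - w % 2
    return x[:h2, :w2].reshape(h2 // 2, 2, w2 // 2, 2, c).max(axis=(1, 3))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class TinyBackboneClassifier:
    """Frozen seeded random-convolution backbone with a trainable dense head.

    Two 3x3 convolution + ReLU + 2x2 max-pool blocks with He-initialized
    fixed filters extract features; only the two dense layers of the head
    are trained (Adam, cross-entropy), matching the frozen-backbone
    transfer-learning protocol at desk scale.
    """

    def __init__(self, head: HeadSpec, config: TrainConfig) -> None:
        self.head = head
        self.config = config
        rng = np.random.default_rng(config.seed)
        self._w_conv1 = rng.normal(0.0, math.sqrt(2.0 / (3 * 3 * 3)), (3, 3, 3, 8))
        self._w_conv2 = rng.normal(0.0, math.sqrt(2.0 / (3 * 3 * 8)), (3, 3, 8, 16))
        self._feat_dim = self._features_one(
            np.zeros((config.side, config.side, 3), dtype=np.uint8)).size
        self._init_head(rng)
        self._mu = np.zeros(self._feat_dim)
        self._sd = np.ones(self._feat_dim)
        self.classes_: list[str] = []

    def _init_head(self, rng: np.random.Generator) -> None:
        d, h, c = self._feat_dim, self.head.hidden_units, self.head.output_units
        self.w1 = rng.normal(0.0, math.sqrt(2.0 / d), (d, h))
        self.b1 = np.zeros(h)
        self.w2 = rng.normal(0.0, math.sqrt(2.0 / h), (h, c))
        self.b2 = np.zeros(c)

    def _features_one(self, pixels: np.ndarray) -> np.ndarray:
        x = pixels.astype(np.float64) / 255.0
        win = sliding_window_view(x, (3, 3), axis=(0, 1))
        x = _relu(np.einsum("ijckl,klcf->ijf", win, self._w_conv1))
        x = _maxpool2(x)
        win = sliding_window_view(x, (3, 3), axis=(0, 1))
        x = _relu(np.einsum("ijckl,klcf->ijf", win, self._w_conv2))
        x = _maxpool2(x)
        return x.ravel()

    def features(self, dataset: LabeledDataset) -> np.ndarray:
        side = self.config.side
        return np.stack([self._features_one(resize(rec, side).pixels)
                         for rec in dataset])

    def fit_normalizer(self, feats: np.ndarray) -> None:
        # center per feature, scale globally: per-feature unit variance would
        # blow up near-dead ReLU dimensions and wreck generalization
        self._mu = feats.mean(axis=0)
        self._sd = np.full(feats.shape[1], feats.std() + 1e-8)

    def _forward(self, x: np.ndarray) -> np.ndarray:
        a1 = _relu(x @ self.w1 + self.b1)
        return _softmax(a1 @ self.w2 + self.b2)

    def predict_proba_features(self, feats: np.ndarray) -> np.ndarray:
        return self._forward((feats - self._mu) / self._sd)

    def predict_proba(self, dataset: LabeledDataset) -> np.ndarray:
        return self.predict_proba_features(self.features(dataset))

    def predict(self, dataset: LabeledDataset) -> list[str]:
        proba = self.predict_proba(dataset)
        return [self.classes_[i] for i in proba.argmax(axis=1)]


def build_classifier(head: HeadSpec, config: TrainConfig):
    """Backbone + flatten + the two-layer dense head, per the config's preset.

    The ``tiny`` backbone is bundled and CPU-only.  Named backbones require
    the optional tensorflow dependency; requesting one without it raises
    :class:`CapabilityError`.
    """
    if config.backbone == "tiny":
        return TinyBackboneClassifier(head, config)
    try:
        import tensorflow  # noqa: F401
    except ImportError as exc:
        raise CapabilityError(
            f"backbone {config.backbone!r} requires the optional deep-learning "
            "dependency (tensorflow); install pestaug with deep-learning support "
            "or use backbone='tiny'") from exc
    return _build_keras_classifier(head, config)


def _build_keras_classifier(head: HeadSpec, config: TrainConfig):
    # exercised only when tensorflow is installed
    from tensorflow import keras

    apps = {"vgg16": keras.applications.VGG16,
            "vgg19": keras.applications.VGG19,
            "resnet50": keras.applications.ResNet50}
    base = apps[config.backbone](include_top=False,
                                 input_shape=(config.side, config.side, 3))
    base.trainable = False
    low, high = config.dropout_range
    model = keras.Sequential([
        base,
        keras.layers.Flatten(),
        keras.layers.Dropout(low),
        keras.layers.Dense(head.hidden_units, activation=head.hidden_activation),
        keras.layers.Dropout(head.dropout),
        keras.layers.Dense(head.output_units, activation=head.output_activation),
    ])
    model.compile(optimizer=keras.optimizers.Adam(config.learning_rate),
                  loss="categorical_crossentropy", metrics=["accuracy"])
    return model


# ---------------------------------------------------------------------------
# Training loop (numpy, Adam)

def _check_disjoint(train: LabeledDataset, validation: LabeledDataset) -> None:
    overlap = train.source_ids() & validation.source_ids()
    if overlap:
        raise LeakageError(
            f"training set contains derivatives of {len(overlap)} validation "
            f"source image(s), e.g. {sorted(overlap)[:3]}")


def train_and_evaluate(classifier: TinyBackboneClassifier,
                       train: LabeledDataset,
                       validation: LabeledDataset,
                       config: TrainConfig) -> EvalResult:
    """Train the dense head and record per-epoch train/validation accuracy.

    Categorical cross-entropy with Adam at the configured learning rate and
    batch size; dropout 0.3 at the backbone-head junction and the head's 0.5
    after the 512-unit layer, active during training only.  Training and
    validation must share the class set and be disjoint by source image.
    """
    if set(train.classes) != set(validation.classes):
        raise ValidationError("train and validation class sets differ")
    _check_disjoint(train, validation)

    classes = list(train.classes)
    classifier.classes_ = classes
    cls_index = {c: i for i, c in enumerate(classes)}

    feats_tr = classifier.features(train)
    classifier.fit_normalizer(feats_tr)
    x_tr = (feats_tr - classifier._mu) / classifier._sd
    x_va = (classifier.features(validation) - classifier._mu) / classifier._sd
    y_tr = np.array([cls_index[r.label] for r in train])
    y_va = np.array([cls_index[r.label] for r in validation])
    onehot = np.eye(len(classes))[y_tr]

    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    n = len(train)
    lr, b1m, b2m, eps = config.learning_rate, 0.9, 0.999, 1e-8
    params = [classifier.w1, classifier.b1, classifier.w2, classifier.b2]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    drop_in, drop_hidden = config.dropout_range[0], classifier.head.dropout

    train_curve: list[float] = []
    val_curve: list[float] = []
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_tr[idx], onehot[idx]
            keep_in = (rng.random(xb.shape) >= drop_in) / (1.0 - drop_in)
            xb = xb * keep_in
            z1 = xb @ classifier.w1 + classifier.b1
            a1 = _relu(z1)
            keep_h = (rng.random(a1.shape) >= drop_hidden) / (1.0 - drop_hidden)
            a1d = a1 * keep_h
            proba = _softmax(a1d @ classifier.w2 + classifier.b2)

            batch = len(idx)
            dlogits = (proba - yb) / batch
            g_w2 = a1d.T @ dlogits
            g_b2 = dlogits.sum(axis=0)
            da1 = (dlogits @ classifier.w2.T) * keep_h * (z1 > 0)
            g_w1 = xb.T @ da1
            g_b1 = da1.sum(axis=0)

            t += 1
            for p, g, mi, vi in zip(params, [g_w1, g_b1, g_w2, g_b2], m, v):
                mi *= b1m
                mi += (1 - b1m) * g
                vi *= b2m
                vi += (1 - b2m) * g * g
                mhat = mi / (1 - b1m ** t)
                vhat = vi / (1 - b2m ** t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)
                if p.ndim == 2:  # decoupled weight decay on the dense matrices
                    p -= lr * config.weight_decay * p

        pred_tr = classifier.predict_proba_features(feats_tr).argmax(axis=1)
        pred_va = classifier._forward(x_va).argmax(axis=1)
        train_curve.append(float((pred_tr == y_tr).mean()))
        val_curve.append(float((pred_va == y_va).mean()))

    return EvalResult(train_curve=train_curve, val_curve=val_curve,
                      final_val_accuracy=val_curve[-1], config=config)
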