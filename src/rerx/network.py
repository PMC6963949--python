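"""Single-hidden-layer backpropagation classifier with attribute pruning.

The rule-extraction pipeline starts from a small feed-forward network:
continuous inputs are standardized, categorical inputs one-hot encoded
(an internal detail -- the interface stays at the attribute level), one
sigmoidal hidden layer feeds a sigmoid output, and training minimizes
cross-entropy plus an L2 weight penalty by full-batch gradient descent
with momentum.  Attribute pruning then iteratively removes the attribute
with the smallest aggregate input-weight magnitude, retrains, and keeps
the removal while training accuracy stays within a tolerance of the
unpruned network's -- the "remove irrelevant and redundant attributes"
step that precedes tree induction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .schema import Cohort, Schema

__all__ = ["NetConfig", "TrainedNetwork", "TrainingError",
           "train_network", "prune_attributes"]


class TrainingError(RuntimeError):
    pass


class NetConfig(BaseModel):
    """Backpropagation hyperparameters."""

    hidden_units: int = Field(default=4, ge=1)
    learning_rate: float = Field(default=0.5, gt=0)
    momentum: float = Field(default=0.9, ge=0, lt=1)
    epochs: int = Field(default=300, ge=0)
    weight_penalty: float = Field(default=1e-4, ge=0)
    init_seed: int = 0
    pruning_accuracy_tolerance: float = Field(default=0.01, ge=0)
    retrain_epochs: int | None = Field(default=None, ge=0)

    @property
    def effective_retrain_epochs(self) -> int:
        return self.retrain_epochs if self.retrain_epochs is not None else max(
            1, self.epochs // 2)


@dataclass
class _Encoder:
    """Attribute-level design-matrix encoding with per-column provenance."""

    attributes: list[str]
    columns: dict[str, list[int]]  # attribute -> column indices
    means: np.ndarray
    sds: np.ndarray
    builders: list  # (attribute, kind, payload) per raw column group

    @classmethod
    def fit(cls, cohort: Cohort, attributes: list[str]) -> "_Encoder":
        cols: dict[str, list[int]] = {}
        builders = []
        mats = []
        j = 0
        for name in attributes:
            attr = cohort.schema[name]
            if attr.is_continuous:
                x = cohort.data[name].to_numpy(dtype=float)[:, None]
                builders.append((name, "cont", None))
                cols[name] = [j]
                j += 1
                mats.append(x)
            else:
                raw = cohort.data[name].to_numpy()
                onehot = np.column_stack(
                    [(raw == lvl).astype(float) for lvl in attr.levels])
                builders.append((name, "cat", attr.levels))
                cols[name] = list(range(j, j + len(attr.levels)))
                j += len(attr.levels)
                mats.append(onehot)
        X = np.hstack(mats) if mats else np.empty((len(cohort), 0))
        means = X.mean(axis=0)
        sds = X.std(axis=0)
        sds[sds == 0] = 1.0
        return cls(list(attributes), cols, means, sds, builders)

    def transform(self, df: pd.DataFrame, schema: Schema) -> np.ndarray:
        mats = []
        for name, kind, levels in self.builders:
            if kind == "cont":
                mats.append(df[name].to_numpy(dtype=float)[:, None])
            else:
                raw = df[name].to_numpy()
                mats.append(np.column_stack(
                    [(raw == lvl).astype(float) for lvl in levels]))
        X = np.hstack(mats) if mats else np.empty((len(df), 0))
        return (X - self.means) / self.sds


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable logistic


@dataclass
class TrainedNetwork:
    """Weights, the active attribute subset and the fitted encoder."""

    schema: Schema
    active_attributes: list[str]
    encoder: _Encoder
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    positive_label: str
    negative_label: str
    training_accuracy: float
    config: NetConfig

    def decision_values(self, df: pd.DataFrame) -> np.ndarray:
        X = self.encoder.transform(df, self.schema)
        h = _sigmoid(X @ self.w1 + self.b1)
        return _sigmoid(h @ self.w2 + self.b2)

    def predict_labels(self, df: pd.DataFrame) -> np.ndarray:
        p = self.decision_values(df)
        return np.where(p >= 0.5, self.positive_label, self.negative_label).astype(object)

    def attribute_weight_magnitude(self, name: str) -> float:
        """Aggregate |input weight| feeding the hidden layer from one attribute."""
        idx = self.encoder.columns[name]
        return float(np.abs(self.w1[idx, :]).sum())


def _fit(X: np.ndarray, t: np.ndarray, config: NetConfig, epochs: int,
         rng: np.random.Generator):
    n, d = X.shape
    h = config.hidden_units
    scale1 = 1.0 / np.sqrt(max(d, 1))
    w1 = rng.normal(0.0, scale1, size=(d, h))
    b1 = np.zeros(h)
    w2 = rng.normal(0.0, 1.0 / np.sqrt(h), size=h)
    b2 = 0.0
    v = [np.zeros_like(w1), np.zeros_like(b1), np.zeros_like(w2), 0.0]
    lr, mom, lam = config.learning_rate, config.momentum, config.weight_penalty
    for _ in range(epochs):
        a1 = _sigmoid(X @ w1 + b1)
        p = _sigmoid(a1 @ w2 + b2)
        delta = (p - t) / n                      # d(mean CE)/d(logit)
        gw2 = a1.T @ delta + lam * w2
        gb2 = delta.sum()
        back = np.outer(delta, w2) * a1 * (1.0 - a1)
        gw1 = X.T @ back + lam * w1
        gb1 = back.sum(axis=0)
        if not np.isfinite(gw1).all() or not np.isfinite(gw2).all():
            raise TrainingError(
                "non-finite gradients during backpropagation "
                f"(lr={lr}, penalty={lam}); lower the learning rate")
        v[0] = mom * v[0] - lr * gw1
        v[1] = mom * v[1] - lr * gb1
        v[2] = mom * v[2] - lr * gw2
        v[3] = mom * v[3] - lr * gb2
        w1 = w1 + v[0]
        b1 = b1 + v[1]
        w2 = w2 + v[2]
        b2 = b2 + v[3]
    return w1, b1, w2, b2


def train_network(cohort: Cohort, config: NetConfig | None = None,
                  attributes: list[str] | None = None,
                  seed: int | None = None) -> TrainedNetwork:
    """Train the classifier on a labeled cohort; seeded and reproducible."""
    config = config or NetConfig()
    if len(cohort) == 0:
        raise ValueError("cannot train on an empty cohort")
    attributes = list(attributes) if attributes is not None else cohort.schema.names
    positive, negative = cohort.schema.class_levels[:2]
    enc = _Encoder.fit(cohort, attributes)
    X = enc.transform(cohort.data, cohort.schema)
    t = (cohort.labels.to_numpy() == positive).astype(float)
    rng = np.random.default_rng(config.init_seed if seed is None else seed)
    w1, b1, w2, b2 = _fit(X, t, config, config.epochs, rng)
    net = TrainedNetwork(cohort.schema, attributes, enc, w1, b1, w2, b2,
                         positive, negative, 0.0, config)
    net.training_accuracy = float(
        (net.predict_labels(cohort.data) == cohort.labels.to_numpy()).mean())
    return net


def prune_attributes(net: TrainedNetwork, cohort: Cohort,
                     tolerance: float | None = None,
                     seed: int | None = None) -> TrainedNetwork:
    """Drop weakly-weighted attributes while accuracy holds.

    Repeatedly removes the active attribute with the smallest aggregate
    input-weight magnitude and retrains (briefly); the removal sticks
    while training accuracy stays within ``tolerance`` of the unpruned
    network's, and the first rejected removal stops the loop.  The
    returned network always satisfies
    ``accuracy >= unpruned accuracy - tolerance``.
    """
    if tolerance is None:
        tolerance = net.config.pruning_accuracy_tolerance
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    baseline = net.training_accuracy
    config = net.config
    retrain = config.model_copy(update={"epochs": config.effective_retrain_epochs})
    current = net
    while len(current.active_attributes) > 1:
        weakest = min(current.active_attributes,
                      key=lambda a: (current.attribute_weight_magnitude(a),
                                     current.active_attributes.index(a)))
        remaining = [a for a in current.active_attributes if a != weakest]
        candidate = train_network(cohort, retrain, attributes=remaining, seed=seed)
        if candidate.training_accuracy >= baseline - tolerance - 1e-12:
            current = candidate
        else:
            break
    return current
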