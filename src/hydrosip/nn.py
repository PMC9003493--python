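"""Minimal fully connected feed-forward networks, trained from scratch.

The classifiers in this pipeline are deliberately tiny — single hidden
layers of 1–20 neurons, tens of weights — so the whole life cycle
(construction, analytic parameter counting, gradient training with binary
cross-entropy, inference) is implemented directly on numpy arrays. A fixed
seed determines initialization and shuffle order exactly, so training is
bit-reproducible.

Hidden activation defaults to ReLU; the output unit is sigmoid (forced by
the binary cross-entropy loss). Features are standardized with constants
stored on the model, so a saved model is self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


@dataclass(frozen=True)
class NetArchitecture:
    """Layer widths of a dense feed-forward network."""

    n_inputs: int
    hidden_sizes: Tuple[int, ...] = ()
    n_outputs: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(self.hidden_sizes))
        if self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("layer sizes must be >= 1")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")

    @property
    def layer_sizes(self) -> Tuple[int, ...]:
        return (self.n_inputs, *self.hidden_sizes, self.n_outputs)


def count_weights(arch: NetArchitecture) -> int:
    """Total trainable parameters: sum of (fan_in + 1) * fan_out, biases included."""
    sizes = arch.layer_sizes
    return int(sum((fi + 1) * fo for fi, fo in zip(sizes, sizes[1:])))


@dataclass
class TrainConfig:
    """Gradient-training recipe for a binary dense classifier."""

    optimizer: str = "sgd"
    epochs: int = 300
    batch_size: int = 100
    train_val_split: float = 0.8
    learning_rate: Optional[float] = None  # None -> 0.01 for sgd, 0.001 for adam
    hidden_activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if not 0 < self.train_val_split < 1:
            raise ValueError("train_val_split must be in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")

    @property
    def lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 0.01 if self.optimizer == "sgd" else 0.001


def _activate(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown hidden activation {name!r}")


def _activate_grad(name: str, z: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (z > 0).astype(float)
    if name == "tanh":
        return 1.0 - np.tanh(z) ** 2
    raise ValueError(f"unknown hidden activation {name!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class DenseNetModel:
    """A trained dense binary classifier with its scaling constants."""

    architecture: NetArchitecture
    weights: List[np.ndarray]
    biases: List[np.ndarray]
    hidden_activation: str = "relu"
    scaler_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    scaler_scale: np.ndarray = field(default=None)  # type: ignore[assignment]
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.scaler_mean is None:
            self.scaler_mean = np.zeros(self.architecture.n_inputs)
        if self.scaler_scale is None:
            self.scaler_scale = np.ones(self.architecture.n_inputs)
        self.scaler_mean = np.asarray(self.scaler_mean, dtype=float)
        self.scaler_scale = np.asarray(self.scaler_scale, dtype=float)
        n_params = sum(w.size for w in self.weights) + sum(b.size for b in self.biases)
        if n_params != count_weights(self.architecture):
            raise ValueError("parameter arrays inconsistent with architecture")

    @property
    def n_parameters(self) -> int:
        return count_weights(self.architecture)

    def _scale(self, X: np.ndarray) -> np.ndarray:
        return (X - self.scaler_mean) / self.scaler_scale

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid probabilities for a (n, n_inputs) batch of RAW features."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.architecture.n_inputs:
            raise ValueError(
                f"expected {self.architecture.n_inputs} features, got {X.shape[1]}"
            )
        a = self._scale(X)
        for w, b in zip(self.weights[:-1], self.biases[:-1]):
            a = _activate(self.hidden_activation, a @ w + b)
        z = a @ self.weights[-1] + self.biases[-1]
        return _sigmoid(z)[:, 0]

    def predict_proba(self, feature_row: Sequence[float]) -> float:
        return float(self.forward(np.asarray(feature_row, dtype=float)[None, :])[0])

    def classify(self, feature_row: Sequence[float]) -> int:
        return int(self.predict_proba(feature_row) >= self.decision_threshold)


def _glorot_init(arch: NetArchitecture, rng: np.random.Generator):
    weights, biases = [], []
    sizes = arch.layer_sizes
    for fi, fo in zip(sizes, sizes[1:]):
        limit = np.sqrt(6.0 / (fi + fo))
        weights.append(rng.uniform(-limit, limit, size=(fi, fo)))
        biases.append(np.zeros(fo))
    return weights, biases


def _stratified_split(y: np.ndarray, train_frac: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_train = max(1, int(round(train_frac * len(idx))))
        n_train = min(n_train, len(idx) - 1) if len(idx) > 1 else n_train
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def _bce(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    eps = 1e-12
    terms = -(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
    return float(np.sum(w * terms) / np.sum(w))


def train(
    X: np.ndarray,
    y: np.ndarray,
    arch: NetArchitecture,
    config: Optional[TrainConfig] = None,
    sample_weight: Optional[np.ndarray] = None,
    decision_threshold: float = 0.5,
) -> Tuple[DenseNetModel, Dict]:
    """Train a dense binary classifier with mini-batch gradient descent.

    Features are standardized over the training split (constants stored on
    the model); the split is a seeded stratified shuffle. Returns the model
    and a history dict with per-epoch training loss and final validation
    loss/accuracy.

    Raises ``ValueError`` for single-class labels or non-finite features.
    """
    config = config or TrainConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) matching y")
    if X.shape[1] != arch.n_inputs:
        raise ValueError(f"architecture expects {arch.n_inputs} inputs, X has {X.shape[1]}")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    if sample_weight is None:
        sample_weight = np.ones(len(y))
    sample_weight = np.asarray(sample_weight, dtype=float).ravel()

    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _stratified_split(y, config.train_val_split, rng)
    Xtr, ytr, wtr = X[train_idx], y[train_idx], sample_weight[train_idx]
    Xval, yval, wval = X[val_idx], y[val_idx], sample_weight[val_idx]

    mean = Xtr.mean(axis=0)
    scale = Xtr.std(axis=0)
    scale[scale == 0] = 1.0
    Ztr = (Xtr - mean) / scale

    weights, biases = _glorot_init(arch, rng)
    act = config.hidden_activation
    lr = config.lr
    if config.optimizer == "adam":
        m_w = [np.zeros_like(w) for w in weights]
        v_w = [np.zeros_like(w) for w in weights]
        m_b = [np.zeros_like(b) for b in biases]
        v_b = [np.zeros_like(b) for b in biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        adam_t = 0

    n = len(ytr)
    history: Dict = {"train_loss": [], "n_train": n, "n_val": len(yval)}
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            xb, yb, wb = Ztr[batch], ytr[batch], wtr[batch]
            # forward, caching pre-activations
            acts = [xb]
            zs = []
            a = xb
            for w, b in zip(weights[:-1], biases[:-1]):
                z = a @ w + b
                zs.append(z)
                a = _activate(act, z)
                acts.append(a)
            z_out = a @ weights[-1] + biases[-1]
            p = _sigmoid(z_out)[:, 0]
            # backward: d(BCE)/dz_out = (p - y), weighted
            wsum = wb.sum()
            delta = ((p - yb) * wb / wsum)[:, None]
            grads_w = [None] * len(weights)
            grads_b = [None] * len(biases)
            for layer in range(len(weights) - 1, -1, -1):
                grads_w[layer] = acts[layer].T @ delta
                grads_b[layer] = delta.sum(axis=0)
                if layer > 0:
                    delta = (delta @ weights[layer].T) * _activate_grad(act, zs[layer - 1])
            if config.optimizer == "sgd":
                for layer in range(len(weights)):
                    weights[layer] -= lr * grads_w[layer]
                    biases[layer] -= lr * grads_b[layer]
            else:
                adam_t += 1
                for layer in range(len(weights)):
                    for g, m, v, param in (
                        (grads_w[layer], m_w[layer], v_w[layer], weights[layer]),
                        (grads_b[layer], m_b[layer], v_b[layer], biases[layer]),
                    ):
                        m *= beta1
                        m += (1 - beta1) * g
                        v *= beta2
                        v += (1 - beta2) * g * g
                        m_hat = m / (1 - beta1 ** adam_t)
                        v_hat = v / (1 - beta2 ** adam_t)
                        param -= lr * m_hat / (np.sqrt(v_hat) + eps)
        # epoch training loss on the full training split
        model_tmp = DenseNetModel(
            architecture=arch, weights=weights, biases=biases,
            hidden_activation=act, scaler_mean=mean, scaler_scale=scale,
            decision_threshold=decision_threshold,
        )
        history["train_loss"].append(_bce(model_tmp.forward(Xtr), ytr, wtr))

    model = DenseNetModel(
        architecture=arch,
        weights=[w.copy() for w in weights],
        biases=[b.copy() for b in biases],
        hidden_activation=act,
        scaler_mean=mean,
        scaler_scale=scale,
        decision_threshold=decision_threshold,
    )
    if len(yval):
        p_val = model.forward(Xval)
        history["val_loss"] = _bce(p_val, yval, wval)
        history["val_accuracy"] = float(np.mean((p_val >= decision_threshold) == yval))
    return model, history
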