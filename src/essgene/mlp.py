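"""Feed-forward neural network for essentiality classification.

The network maps the 89 standardized sequence features through a stack of
fully connected hidden layers (affine -> ReLU -> dropout) to a two-unit
output whose normalized-exponential activation yields a probability pair
summing to one; the second unit is the probability that the gene is
essential.  Training minimizes binary cross-entropy with the Adadelta
optimizer and stops early when validation loss stops improving, restoring
the best-validation weights.

The default architecture is six hidden layers of widths
128, 256, 512, 1024, 1024, 1024 with dropout rate 0.3, at most 100 epochs
and patience 10.  All of it is plain NumPy: the model is small enough that
a CPU forward/backward pass in float32 is entirely adequate.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ConfigurationError,
    InvalidInputError,
    StateError,
    TrainingFailureError,
)

DEFAULT_HIDDEN_DIMS = (128, 256, 512, 1024, 1024, 1024)


@dataclass(frozen=True)
class ModelConfig:
    """Hyper-parameters of the classifier.

    The defaults are the selected configuration of the tuned architecture:
    six hidden layers (128..1024), dropout 0.3, Adadelta, up to 100 epochs
    with early stopping.  The batch size was tuned but its selected value
    was not reported; 256 is the package default.
    """

    input_dim: int = 89
    hidden_dims: tuple[int, ...] = DEFAULT_HIDDEN_DIMS
    dropout_rate: float = 0.3
    max_epochs: int = 100
    early_stopping_patience: int = 10
    batch_size: int = 256
    optimizer: str = "adadelta"
    seed: int = 0

    def __post_init__(self):
        if not self.hidden_dims or any(h <= 0 for h in self.hidden_dims):
            raise ConfigurationError(
                f"hidden_dims must be non-empty and positive: {self.hidden_dims}"
            )
        if not 0 <= self.dropout_rate < 1:
            raise ConfigurationError(
                f"dropout_rate must be in [0, 1): {self.dropout_rate}"
            )
        if self.optimizer not in ("adadelta", "sgd"):
            raise ConfigurationError(f"unsupported optimizer: {self.optimizer!r}")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _Adadelta:
    """Adadelta accumulators (rho=0.95, eps=1e-6, lr=1); no learning rate
    needs to be chosen, which is why the optimizer was preferred."""

    def __init__(self, params: list[np.ndarray], rho=0.95, eps=1e-6):
        self.rho, self.eps = rho, eps
        self.eg2 = [np.zeros_like(p) for p in params]
        self.ed2 = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        for p, g, eg2, ed2 in zip(params, grads, self.eg2, self.ed2):
            eg2 *= self.rho
            eg2 += (1 - self.rho) * g * g
            delta = -np.sqrt((ed2 + self.eps) / (eg2 + self.eps)) * g
            ed2 *= self.rho
            ed2 += (1 - self.rho) * delta * delta
            p += delta


class _SGD:
    def __init__(self, params, lr=0.01):
        self.lr = lr

    def step(self, params, grads):
        for p, g in zip(params, grads):
            p -= self.lr * g


@dataclass
class TrainedModel:
    """Network parameters plus the configuration and training history."""

    config: ModelConfig
    weights: list[np.ndarray] = field(default_factory=list)
    biases: list[np.ndarray] = field(default_factory=list)
    history: dict[str, list[float]] = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    stopped_epoch: int = 0
    trained: bool = False

    @property
    def layer_dims(self) -> list[int]:
        return [self.config.input_dim, *self.config.hidden_dims, 2]

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def build_model(config: ModelConfig) -> TrainedModel:
    """Initialize an untrained network from a seeded He-normal scheme."""
    rng = np.random.default_rng(config.seed)
    dims = [config.input_dim, *config.hidden_dims, 2]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        weights.append(w.astype(np.float32))
        biases.append(np.zeros(fan_out, dtype=np.float32))
    return TrainedModel(config=config, weights=weights, biases=biases)


def _forward(
    model: TrainedModel,
    x: np.ndarray,
    rng: np.random.Generator | None = None,
):
    """Forward pass; dropout is applied only when an rng is supplied.

    Returns class probabilities and, in training mode, the cached layer
    activations and dropout masks needed by backprop.
    """
    p = model.config.dropout_rate
    activations = [x]
    masks = []
    h = x
    n_hidden = len(model.config.hidden_dims)
    for i in range(n_hidden):
        z = h @ model.weights[i] + model.biases[i]
        h = np.maximum(z, 0.0)
        if rng is not None and p > 0:
            mask = (rng.random(h.shape) >= p) / (1.0 - p)  # inverted dropout
            h = h * mask
            masks.append(mask.astype(np.float32))
        else:
            masks.append(None)
        activations.append(h)
    logits = h @ model.weights[-1] + model.biases[-1]
    probs = _softmax(logits.astype(np.float64))
    return probs, activations, masks


def _cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true class."""
    eps = 1e-12
    return float(-np.mean(np.log(probs[np.arange(len(labels)), labels] + eps)))


def _backward(model, probs, labels, activations, masks):
    """Gradients of mean cross-entropy w.r.t. all weights and biases."""
    n = len(labels)
    grad_w = [None] * len(model.weights)
    grad_b = [None] * len(model.biases)
    delta = probs.copy()
    delta[np.arange(n), labels] -= 1.0
    delta = (delta / n).astype(np.float32)
    # output layer
    grad_w[-1] = activations[-1].T @ delta
    grad_b[-1] = delta.sum(axis=0)
    back = delta @ model.weights[-1].T
    for i in range(len(model.config.hidden_dims) - 1, -1, -1):
        if masks[i] is not None:
            back = back * masks[i]
        back = back * (activations[i + 1] > 0)  # ReLU gate (post-dropout sign safe: mask >= 0)
        grad_w[i] = activations[i].T @ back
        grad_b[i] = back.sum(axis=0)
        if i > 0:
            back = back @ model.weights[i].T
    return grad_w, grad_b


def train(
    model: TrainedModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
) -> TrainedModel:
    """Train with minibatch Adadelta and early stopping.

    Stops after ``max_epochs`` or once validation loss has failed to
    improve for ``early_stopping_patience`` consecutive epochs; the
    parameters of the best-validation epoch are restored.
    """
    cfg = model.config
    x_train = np.asarray(x_train, dtype=np.float32)
    x_val = np.asarray(x_val, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.int64)
    y_val = np.asarray(y_val, dtype=np.int64)
    if len(x_train) == 0 or len(x_val) == 0:
        raise InvalidInputError("train and validation partitions must be non-empty")
    if x_train.shape[1] != cfg.input_dim:
        raise InvalidInputError(
            f"feature dimension {x_train.shape[1]} != configured {cfg.input_dim}"
        )

    rng = np.random.default_rng(cfg.seed + 1)
    params = model.weights + model.biases
    opt = _Adadelta(params) if cfg.optimizer == "adadelta" else _SGD(params)

    # baseline: validation loss of the untrained network, so an epoch that
    # fails to beat it already counts as non-improving
    init_probs, _, _ = _forward(model, x_val, rng=None)
    best_val = _cross_entropy(init_probs, y_val)
    best_params = [p.copy() for p in params]
    best_epoch = 0
    bad_epochs = 0
    history = {"train_loss": [], "val_loss": []}

    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(len(x_train))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            probs, acts, masks = _forward(model, xb, rng=rng)
            loss = _cross_entropy(probs, yb)
            if not np.isfinite(loss):
                raise TrainingFailureError(
                    f"non-finite training loss at epoch {epoch}", epoch=epoch
                )
            grad_w, grad_b = _backward(model, probs, yb, acts, masks)
            opt.step(params, grad_w + grad_b)
            epoch_loss += loss
            n_batches += 1
        val_probs, _, _ = _forward(model, x_val, rng=None)
        val_loss = _cross_entropy(val_probs, y_val)
        if not np.isfinite(val_loss):
            raise TrainingFailureError(
                f"non-finite validation loss at epoch {epoch}", epoch=epoch
            )
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-9:
            best_val = val_loss
            best_params = [p.copy() for p in params]
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= max(cfg.early_stopping_patience, 1):
                break

    for p, best in zip(params, best_params):
        p[...] = best
    return replace(
        model,
        history=history,
        stopped_epoch=best_epoch,
        trained=True,
    )


def predict_proba(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Probability of the essential class per record (dropout disabled)."""
    if not model.trained:
        raise StateError("model has not been trained")
    x = np.asarray(features, dtype=np.float32)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != model.config.input_dim:
        raise InvalidInputError(
            f"feature dimension {x.shape[1]} != configured {model.config.input_dim}"
        )
    probs, _, _ = _forward(model, x, rng=None)
    return probs[:, 1]


def predict_proba_pairs(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """The full (non-essential, essential) probability pair per record."""
    if not model.trained:
        raise StateError("model has not been trained")
    x = np.asarray(features, dtype=np.float32)
    probs, _, _ = _forward(model, x, rng=None)
    return probs
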