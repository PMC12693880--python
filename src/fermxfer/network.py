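"""From-scratch fully connected sigmoid regressor.

A plain feedforward network with logistic-sigmoid activations on every
layer, including the output layer, trained by full-batch gradient descent
on the half-sum-of-squares loss

    E = 1/2 * sum_k (y_k - yhat_k)^2 .

A mean-normalized squared error is exposed separately for reporting and
for transfer fine-tuning.  Because the output is a sigmoid, targets must be
min-max scaled into a margin-padded interval (default [0.05, 0.95]) before
training; :class:`ScalerPair` bundles the input standardizer and the target
scaler and inverts predictions back to physical units.

Backpropagation is reverse-mode chain rule through the sigmoid layers; it
is verified against central finite differences in the test suite.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.preprocessing import MinMaxScaler, StandardScaler

__all__ = [
    "NetworkArch",
    "NetworkParams",
    "ScalerPair",
    "init_params",
    "forward",
    "sse_loss",
    "mse_loss",
    "backward",
    "backprop_from",
    "gd_step",
    "train",
]


@dataclass(frozen=True)
class NetworkArch:
    """Layer widths of the feedforward soft-sensor model."""

    n_inputs: int
    hidden_widths: tuple[int, ...]
    n_outputs: int = 1
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.n_inputs < 1 or self.n_outputs < 1:
            raise ValueError("n_inputs and n_outputs must be >= 1")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("all hidden widths must be >= 1")
        if self.activation != "sigmoid":
            raise ValueError("only the sigmoid activation is supported")

    @property
    def n_layers(self) -> int:
        """Number of weight layers (hidden layers + output layer)."""
        return len(self.hidden_widths) + 1

    @property
    def layer_widths(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden_widths, self.n_outputs)


@dataclass
class NetworkParams:
    """Per-layer weights (out x in) and biases, plus the architecture."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    arch: NetworkArch

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            weights=[w.copy() for w in self.weights],
            biases=[b.copy() for b in self.biases],
            arch=self.arch,
        )

    def check_shapes(self) -> None:
        widths = self.arch.layer_widths
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (widths[l + 1], widths[l]) or b.shape != (widths[l + 1],):
                raise ValueError(f"layer {l + 1} parameter shapes do not chain")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {l + 1} parameters are not finite")


def init_params(arch: NetworkArch, init_range: float,
                rng: np.random.Generator | int) -> NetworkParams:
    """Seeded uniform(-r, r) initialization of all weights and biases."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    widths = arch.layer_widths
    weights = [rng.uniform(-init_range, init_range, size=(widths[l + 1], widths[l]))
               for l in range(arch.n_layers)]
    biases = [rng.uniform(-init_range, init_range, size=widths[l + 1])
              for l in range(arch.n_layers)]
    return NetworkParams(weights=weights, biases=biases, arch=arch)


def forward(params: NetworkParams, X: np.ndarray
            ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Layer-wise a_l = sigmoid(W_l a_{l-1} + b_l).

    Returns the final output and the list of activations
    ``[X, a_1, ..., a_L]`` for backpropagation and feature extraction.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != params.arch.n_inputs:
        raise ValueError(
            f"X has {X.shape[1]} columns, network expects {params.arch.n_inputs}")
    activations = [X]
    a = X
    for w, b in zip(params.weights, params.biases):
        a = expit(a @ w.T + b)
        activations.append(a)
    return a, activations


def sse_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Half sum of squared residuals over all samples and outputs."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    return 0.5 * float(((pred - truth) ** 2).sum())


def mse_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean squared error (reporting / fine-tuning convention)."""
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    return float(((pred - truth) ** 2).mean())


def backprop_from(params: NetworkParams, activations: list[np.ndarray],
                  delta: np.ndarray, layer: int
                  ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Chain-rule gradients given dLoss/d(activation) at ``layer`` (1-based).

    ``delta`` is the loss gradient with respect to the *post-activation*
    output of ``layer``.  Returns full-length gradient lists with zeros for
    layers above ``layer``.
    """
    L = params.arch.n_layers
    if not 1 <= layer <= L:
        raise ValueError(f"layer must be in [1, {L}]")
    dW = [np.zeros_like(w) for w in params.weights]
    db = [np.zeros_like(b) for b in params.biases]
    a_out = activations[layer]
    d = np.asarray(delta, dtype=float) * a_out * (1.0 - a_out)  # sigmoid'
    for l in range(layer - 1, -1, -1):
        dW[l] = d.T @ activations[l]
        db[l] = d.sum(axis=0)
        if l > 0:
            a_prev = activations[l]
            d = (d @ params.weights[l]) * a_prev * (1.0 - a_prev)
    return dW, db


def backward(params: NetworkParams, X: np.ndarray, Y: np.ndarray
             ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of the half-sum-of-squares loss for a full batch."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    pred, activations = forward(params, X)
    if pred.shape != Y.shape:
        raise ValueError("Y shape does not match network output")
    delta = pred - Y  # d(sse_loss)/d(pred)
    dW, db = backprop_from(params, activations, delta, params.arch.n_layers)
    for g in dW + db:
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient encountered")
    return dW, db


def _lr_per_layer(lr, n_layers: int) -> np.ndarray:
    lr = np.asarray(lr, dtype=float)
    if lr.ndim == 0:
        lr = np.full(n_layers, float(lr))
    if lr.shape != (n_layers,):
        raise ValueError(f"learning rate must be scalar or length {n_layers}")
    if np.any(lr < 0):
        raise ValueError("learning rates must be nonnegative")
    return lr


def gd_step(params: NetworkParams, grads, lr) -> NetworkParams:
    """One descent update w <- w - eta * grad (per-layer eta allowed)."""
    dW, db = grads
    eta = _lr_per_layer(lr, params.arch.n_layers)
    out = params.copy()
    for l in range(params.arch.n_layers):
        if eta[l] == 0.0:
            continue  # frozen layer: bit-identical parameters
        out.weights[l] -= eta[l] * dW[l]
        out.biases[l] -= eta[l] * db[l]
    return out


def train(params: NetworkParams, X: np.ndarray, Y: np.ndarray,
          epochs: int, lr, loss: str = "sse"
          ) -> tuple[NetworkParams, list[float]]:
    """Full-batch gradient descent for a fixed number of epochs.

    ``loss`` selects the training convention: ``"sse"`` (half-sum form) or
    ``"mse"`` (mean form).  The recorded history uses the same convention.
    Deterministic: no randomness is consumed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("training data is empty")
    if loss not in ("sse", "mse"):
        raise ValueError("loss must be 'sse' or 'mse'")
    scale = 1.0 if loss == "sse" else 2.0 / (Y.shape[0] * Y.shape[1])
    loss_fn = sse_loss if loss == "sse" else mse_loss

    params = params.copy()
    history: list[float] = []
    for epoch in range(int(epochs)):
        pred, activations = forward(params, X)
        delta = (pred - Y) * scale
        dW, db = backprop_from(params, activations, delta,
                               params.arch.n_layers)
        params = gd_step(params, (dW, db), lr)
        value = loss_fn(forward(params, X)[0], Y)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"training diverged (non-finite loss) at epoch {epoch + 1}")
        history.append(value)
    return params, history


@dataclass
class ScalerPair:
    """Input standardizer + target min-max scaler into a sigmoid-safe band.

    Fitted on training data only.  Targets are mapped into
    ``[margin, 1 - margin]`` so a sigmoid output can represent them; the
    inverse transform restores physical units.
    """

    margin: float = 0.05
    input_scaler: StandardScaler = field(default_factory=StandardScaler)
    target_scaler: MinMaxScaler | None = None

    @staticmethod
    def _as_2d(Y: np.ndarray) -> np.ndarray:
        Y = np.asarray(Y, dtype=float)
        return Y[:, None] if Y.ndim == 1 else Y

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "ScalerPair":
        self.input_scaler.fit(X)
        self.target_scaler = MinMaxScaler(
            feature_range=(self.margin, 1.0 - self.margin)).fit(self._as_2d(Y))
        return self

    def scale_X(self, X: np.ndarray) -> np.ndarray:
        return self.input_scaler.transform(np.atleast_2d(X))

    def scale_y(self, Y: np.ndarray) -> np.ndarray:
        return self.target_scaler.transform(self._as_2d(Y))

    def unscale_y(self, Y: np.ndarray) -> np.ndarray:
        return self.target_scaler.inverse_transform(np.atleast_2d(Y))
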