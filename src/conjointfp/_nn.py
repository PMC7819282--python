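"""Minimal feed-forward / LSTM regression engine on NumPy.

Implements exactly what the two neural model families need: dense layers
with a small set of activations (softsign, relu, linear, tanh), inverted
dropout, a single-timestep LSTM layer, mean-squared-error loss and the
Adam optimizer (learning rate 0.001 by default). Everything is seeded and
single-threaded, so repeated runs with the same seed and data are
bit-identical.

Layers are declared as lightweight specs and weights are materialized
lazily at the first ``fit``/``predict`` call; architecture queries (layer
widths, counts) therefore cost nothing even for very wide layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NeuralNet", "dense", "dropout", "lstm", "ACTIVATIONS"]


def _softsign(x):
    return x / (1.0 + np.abs(x))


def _softsign_grad(x):
    return 1.0 / (1.0 + np.abs(x)) ** 2


def _linear(x):
    return x


def _linear_grad(x):
    return np.ones_like(x)


def _relu(x):
    return np.maximum(x, 0.0)


def _relu_grad(x):
    return (x > 0).astype(x.dtype)


def _tanh_grad(x):
    return 1.0 - np.tanh(x) ** 2


# named module-level functions so fitted models pickle cleanly
ACTIVATIONS = {
    "linear": (_linear, _linear_grad),
    "relu": (_relu, _relu_grad),
    "tanh": (np.tanh, _tanh_grad),
    "softsign": (_softsign, _softsign_grad),
}


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # dense | dropout | lstm
    units: int = 0
    activation: str = "linear"
    rate: float = 0.0


def dense(units: int, activation: str = "linear") -> LayerSpec:
    if activation not in ACTIVATIONS:
        raise ValueError(
            f"unknown activation {activation!r}; choose from {sorted(ACTIVATIONS)}"
        )
    return LayerSpec(kind="dense", units=units, activation=activation)


def dropout(rate: float) -> LayerSpec:
    if not 0.0 <= rate < 1.0:
        raise ValueError("dropout rate must be in [0, 1)")
    return LayerSpec(kind="dropout", rate=rate)


def lstm(units: int) -> LayerSpec:
    """Single-timestep LSTM layer (the whole vector is one timestep)."""
    return LayerSpec(kind="lstm", units=units)


class _Dense:
    def __init__(self, spec: LayerSpec, n_in: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + spec.units))
        self.W = rng.uniform(-limit, limit, size=(n_in, spec.units))
        self.b = np.zeros(spec.units)
        self.act, self.act_grad = ACTIVATIONS[spec.activation]
        self.n_out = spec.units

    def forward(self, x, training):
        self._x = x
        self._z = x @ self.W + self.b
        return self.act(self._z)

    def backward(self, grad):
        dz = grad * self.act_grad(self._z)
        self.grads = [self._x.T @ dz, dz.sum(axis=0)]
        return dz @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]


class _Dropout:
    def __init__(self, spec: LayerSpec, n_in: int, rng: np.random.Generator):
        self.rate = spec.rate
        self.rng = rng
        self.n_out = n_in
        self.params: list = []
        self.grads: list = []

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class _LSTM:
    """One LSTM step from a zero initial state.

    With a single timestep the recurrent weights U see only the zero
    initial hidden state, so they receive no gradient; they are kept for
    architectural faithfulness but stay at their initial values.
    """

    def __init__(self, spec: LayerSpec, n_in: int, rng: np.random.Generator):
        h = spec.units
        limit = np.sqrt(6.0 / (n_in + h))
        self.W = rng.uniform(-limit, limit, size=(n_in, 4 * h))
        self.U = rng.uniform(-limit, limit, size=(h, 4 * h))
        self.b = np.zeros(4 * h)
        self.h = h
        self.n_out = h

    def forward(self, x, training):
        h = self.h
        self._x = x
        z = x @ self.W + self.b  # h_prev = 0 so U contributes nothing
        self._i = _sigmoid(z[:, :h])
        self._g = np.tanh(z[:, 2 * h : 3 * h])
        self._o = _sigmoid(z[:, 3 * h :])
        self._c = self._i * self._g  # f-gate multiplies the zero initial cell
        self._tc = np.tanh(self._c)
        return self._o * self._tc

    def backward(self, grad):
        h = self.h
        do = grad * self._tc
        dc = grad * self._o * (1.0 - self._tc**2)
        di = dc * self._g
        dg = dc * self._i
        dz = np.zeros((grad.shape[0], 4 * h))
        dz[:, :h] = di * self._i * (1.0 - self._i)
        dz[:, 2 * h : 3 * h] = dg * (1.0 - self._g**2)
        dz[:, 3 * h :] = do * self._o * (1.0 - self._o)
        self.grads = [self._x.T @ dz, dz.sum(axis=0)]
        return dz @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]


_LAYER_CLASSES = {"dense": _Dense, "dropout": _Dropout, "lstm": _LSTM}


class NeuralNet:
    """A sequential network trained with Adam on mean squared error."""

    def __init__(self, input_len: int, layers: list[LayerSpec], seed: int = 0):
        if input_len <= 0:
            raise ValueError("input_len must be positive")
        self.input_len = input_len
        self.layer_specs = list(layers)
        self.seed = seed
        self._layers: list | None = None
        self.loss_history: list[tuple[float, float | None]] = []

    # -- architecture queries (no weight allocation) --
    @property
    def layer_widths(self) -> list[int]:
        """Output width of each layer, in order, computed from the specs."""
        widths = []
        w = self.input_len
        for spec in self.layer_specs:
            w = w if spec.kind == "dropout" else spec.units
            widths.append(w)
        return widths

    @property
    def n_layers(self) -> int:
        return len(self.layer_specs)

    def _materialize(self):
        if self._layers is not None:
            return
        rng = np.random.default_rng(self.seed)
        self._layers = []
        n_in = self.input_len
        for spec in self.layer_specs:
            layer = _LAYER_CLASSES[spec.kind](spec, n_in, rng)
            n_in = layer.n_out
            self._layers.append(layer)
        self._shuffle_rng = np.random.default_rng(self.seed + 1)

    def _forward(self, X, training):
        out = X
        for layer in self._layers:
            out = layer.forward(out, training)
        return out

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 100,
        batch_size: int = 32,
        learning_rate: float = 0.001,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> "NeuralNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of rows")
        if X.shape[1] != self.input_len:
            raise ValueError(
                f"X has {X.shape[1]} columns, network expects {self.input_len}"
            )
        if not np.isfinite(y).all():
            raise ValueError("targets contain non-finite values")
        self._materialize()
        params = [p for layer in self._layers for p in layer.params]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = X.shape[0]
        self.loss_history = []
        for _ in range(epochs):
            order = self._shuffle_rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = X[idx], y[idx]
                pred = self._forward(xb, training=True).ravel()
                err = pred - yb
                epoch_loss += float(err @ err)
                grad = (2.0 * err / len(idx))[:, None]
                for layer in reversed(self._layers):
                    grad = layer.backward(grad)
                grads = [g for layer in self._layers for g in layer.grads]
                step += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    mi *= beta1
                    mi += (1 - beta1) * g
                    vi *= beta2
                    vi += (1 - beta2) * g * g
                    mhat = mi / (1 - beta1**step)
                    vhat = vi / (1 - beta2**step)
                    p -= learning_rate * mhat / (np.sqrt(vhat) + eps)
            train_loss = epoch_loss / n
            val_loss = None
            if validation is not None:
                vp = self._forward(np.asarray(validation[0], dtype=float), False).ravel()
                verr = vp - np.asarray(validation[1], dtype=float).ravel()
                val_loss = float(verr @ verr) / len(verr)
            self.loss_history.append((train_loss, val_loss))
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_len:
            raise ValueError(
                f"X must be 2-D with {self.input_len} columns (got {X.shape})"
            )
        if X.shape[0] == 0:
            return np.empty(0)
        self._materialize()
        return self._forward(X, training=False).ravel()
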