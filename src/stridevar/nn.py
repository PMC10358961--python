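"""Minimal feed-forward / 1-D convolutional network core.

A small, dependency-free building block for the two regression models
in :mod:`stridevar.estimators`: layers keep explicit parameter and
gradient lists, training uses Adam on mini-batch mean-squared error
with early stopping on a validation set, and every source of
randomness (initialisation, shuffling, dropout) comes from one seeded
generator so training is bit-reproducible.
"""
from __future__ import annotations

import copy
import json
from typing import List, Optional, Sequence

import numpy as np

__all__ = [
    "Dense",
    "Conv1D",
    "MaxPool1D",
    "ReLU",
    "Flatten",
    "BatchNorm",
    "Dropout",
    "Sequential",
]


class Layer:
    params: List[np.ndarray]
    grads: List[np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He initialisation, ReLU-friendly
        w = rng.normal(0.0, scale, (n_in, n_out))
        b = np.zeros(n_out)
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def forward(self, x, training):
        self._x = x
        return x @ self.params[0] + self.params[1]

    def backward(self, g):
        self.grads[0][:] = self._x.T @ g
        self.grads[1][:] = g.sum(axis=0)
        return g @ self.params[0].T


class Conv1D(Layer):
    """Valid 1-D convolution over (N, C, L) via an im2col matmul."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * kernel))
        w = rng.normal(0.0, scale, (c_in * kernel, c_out))
        b = np.zeros(c_out)
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.params = [w, b]
        self.grads = [np.zeros_like(w), np.zeros_like(b)]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # (N, C, L) -> (N, L', C*k)
        win = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=2)
        return win.transpose(0, 2, 1, 3).reshape(x.shape[0], -1, self.c_in * self.kernel)

    def forward(self, x, training):
        self._cols = self._im2col(x)
        out = self._cols @ self.params[0] + self.params[1]
        return out.transpose(0, 2, 1)  # (N, c_out, L')

    def backward(self, g):
        g = np.ascontiguousarray(g.transpose(0, 2, 1))  # (N, L', c_out)
        n, lp, _ = g.shape
        gc = g.reshape(-1, self.c_out)
        cols = self._cols.reshape(-1, self.c_in * self.kernel)
        self.grads[0][:] = cols.T @ gc
        self.grads[1][:] = gc.sum(axis=0)
        gcols = (gc @ self.params[0].T).reshape(n, lp, self.c_in, self.kernel)
        # scatter the column gradients back onto the signal axis
        gx = np.zeros((n, self.c_in, lp + self.kernel - 1))
        for k in range(self.kernel):
            gx[:, :, k : k + lp] += gcols[:, :, :, k].transpose(0, 2, 1)
        return gx


class MaxPool1D(Layer):
    def __init__(self, pool: int) -> None:
        super().__init__()
        self.pool = pool

    def forward(self, x, training):
        n, c, l = x.shape
        lp = l // self.pool
        xr = x[:, :, : lp * self.pool].reshape(n, c, lp, self.pool)
        self._arg = xr.argmax(axis=3)
        self._shape = x.shape
        return xr.max(axis=3)

    def backward(self, g):
        n, c, lp = g.shape
        gx = np.zeros((n, c, lp, self.pool))
        idx = np.indices((n, c, lp))
        gx[idx[0], idx[1], idx[2], self._arg] = g
        out = np.zeros(self._shape)
        out[:, :, : lp * self.pool] = gx.reshape(n, c, lp * self.pool)
        return out


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class BatchNorm(Layer):
    """Batch normalisation over the feature axis of (N, D) inputs."""

    def __init__(self, n_feat: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        gamma, beta = np.ones(n_feat), np.zeros(n_feat)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(n_feat)
        self.running_var = np.ones(n_feat)

    def forward(self, x, training):
        if training:
            mu, var = x.mean(axis=0), x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._xhat = (x - mu) / np.sqrt(var + self.eps)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        return self.params[0] * self._xhat + self.params[1]

    def backward(self, g):
        n = g.shape[0]
        self.grads[0][:] = (g * self._xhat).sum(axis=0)
        self.grads[1][:] = g.sum(axis=0)
        gx = self.params[0] * self._istd / n * (
            n * g - g.sum(axis=0) - self._xhat * (g * self._xhat).sum(axis=0)
        )
        return gx


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training):
        if not training or self.rate == 0:
            return x
        self._mask = self.rng.random(x.shape) >= self.rate
        return x * self._mask / (1.0 - self.rate)

    def backward(self, g):
        return g * self._mask / (1.0 - self.rate)


class Sequential:
    """A layer stack trained with Adam on mean-squared error."""

    def __init__(self, layers: Sequence[Layer], rng: Optional[np.random.Generator] = None):
        self.layers = list(layers)
        self.rng = rng or np.random.default_rng(0)
        self._adam_m = [np.zeros_like(p) for l in self.layers for p in l.params]
        self._adam_v = [np.zeros_like(p) for l in self.layers for p in l.params]
        self._adam_t = 0

    def predict(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        outs = []
        for i in range(0, len(x), batch_size):
            h = x[i : i + batch_size]
            for layer in self.layers:
                h = layer.forward(h, training=False)
            outs.append(h)
        return np.concatenate(outs, axis=0)

    def _step(self, xb: np.ndarray, yb: np.ndarray, lr: float, weight_decay: float) -> float:
        h = xb
        for layer in self.layers:
            h = layer.forward(h, training=True)
        diff = h - yb
        loss = float(np.mean(diff**2))
        g = 2.0 * diff / diff.size
        for layer in reversed(self.layers):
            g = layer.backward(g)
        # Adam update
        self._adam_t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        i = 0
        for layer in self.layers:
            for p, gr in zip(layer.params, layer.grads):
                self._adam_m[i] = b1 * self._adam_m[i] + (1 - b1) * gr
                self._adam_v[i] = b2 * self._adam_v[i] + (1 - b2) * gr**2
                mhat = self._adam_m[i] / (1 - b1**self._adam_t)
                vhat = self._adam_v[i] / (1 - b2**self._adam_t)
                p -= lr * (mhat / (np.sqrt(vhat) + eps) + weight_decay * p)
                i += 1
        return loss

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        epochs: int = 100,
        batch_size: int = 128,
        lr: float = 1e-3,
        patience: int = 10,
        weight_decay: float = 0.0,
        verbose: bool = False,
    ) -> List[float]:
        """Train with early stopping; the best validation state is restored.

        ``weight_decay`` applies decoupled L2 shrinkage to all
        parameters alongside the Adam update.
        """
        best_val, best_state, wait = np.inf, None, 0
        history: List[float] = []
        for epoch in range(epochs):
            order = self.rng.permutation(len(x))
            for i in range(0, len(x), batch_size):
                idx = order[i : i + batch_size]
                self._step(x[idx], y[idx], lr, weight_decay)
            val = float(np.mean((self.predict(x_val) - y_val) ** 2))
            history.append(val)
            if verbose:  # pragma: no cover
                print(f"epoch {epoch}: val mse {val:.5f}")
            if val < best_val - 1e-7:
                best_val, wait = val, 0
                best_state = self.get_state()
            else:
                wait += 1
                if wait >= patience:
                    break
        if best_state is not None:
            self.set_state(best_state)
        return history

    # -- state (parameters + batch-norm statistics), JSON-serialisable --
    def get_state(self) -> dict:
        state = {"params": [[p.tolist() for p in l.params] for l in self.layers]}
        state["running"] = [
            {"mean": l.running_mean.tolist(), "var": l.running_var.tolist()}
            if isinstance(l, BatchNorm)
            else None
            for l in self.layers
        ]
        return copy.deepcopy(state)

    def set_state(self, state: dict) -> None:
        for layer, ps, run in zip(self.layers, state["params"], state["running"]):
            for p, new in zip(layer.params, ps):
                p[:] = np.asarray(new)
            if run is not None and isinstance(layer, BatchNorm):
                layer.running_mean = np.asarray(run["mean"])
                layer.running_var = np.asarray(run["var"])

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.get_state(), fh)

    def load(self, path: str) -> None:
        with open(path) as fh:
            self.set_state(json.load(fh))
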