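"""A small numpy neural-network core.

Implements exactly the layers the pipeline's trainable components need —
valid 3x3 convolution, 2x2 max pooling, global average pooling, batch
normalization, dropout, dense layers, softmax — together with the Adam
optimizer, the iterative learning-rate decay ``lr <- lr / (1 + decay)``
applied after each epoch, cross-entropy losses, and early stopping on
validation accuracy. Everything is deterministic given a seed.

The networks built on top of this (the fine-tuning head and the two image
aggregation networks) have at most a few hundred thousand parameters and
train in seconds on a CPU, so no deep-learning runtime is required.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class TrainConfig:
    """Optimization hyperparameters.

    ``decay`` defaults to ``lr0 / max_epochs``; the learning rate starts at
    ``lr0`` and is divided by ``(1 + decay)`` after every epoch. Adam betas
    default to (0.8, 0.99). Early stopping triggers when validation accuracy
    fails to improve by more than ``early_stop_tol`` for
    ``early_stop_patience`` consecutive epochs; the best-epoch weights are
    restored.
    """

    lr0: float = 0.008
    decay: float | None = None
    max_epochs: int = 60
    early_stop_patience: int = 5
    early_stop_tol: float = 1e-3
    batch_size: int = 32
    dropout: float = 0.4
    adam_beta1: float = 0.8
    adam_beta2: float = 0.99
    l2: float = 1e-4
    seed: int = 0

    def effective_decay(self) -> float:
        return self.lr0 / self.max_epochs if self.decay is None else self.decay


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class Layer:
    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _init_weight(shape: tuple[int, ...], fan_in: int, fan_out: int, init: str, rng: np.random.Generator) -> np.ndarray:
    if init == "he_uniform":
        limit = np.sqrt(6.0 / fan_in)
    elif init == "glorot_uniform":
        limit = np.sqrt(6.0 / (fan_in + fan_out))
    else:
        raise ValueError(f"unknown init {init!r}")
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(
        self,
        n_in: int,
        n_out: int,
        activation: str | None = None,
        l2: float = 0.0,
        init: str = "glorot_uniform",
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.activation = activation
        self.l2 = l2
        self.params = {
            "W": _init_weight((n_in, n_out), n_in, n_out, init, rng),
            "b": np.zeros(n_out),
        }

    def forward(self, x, training, rng):
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        if self.activation == "sigmoid":
            self._a = sigmoid(z)
            return self._a
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        if self.activation is None:
            return z
        raise ValueError(f"unknown activation {self.activation!r}")

    def backward(self, grad):
        if self.activation == "sigmoid":
            grad = grad * self._a * (1.0 - self._a)
        elif self.activation == "relu":
            grad = grad * (self._z > 0)
        self.grads["W"] = self._x.T @ grad + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Conv2D(Layer):
    """Valid 3x3 convolution, stride 1, NHWC layout, optional ReLU."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        activation: str | None = "relu",
        l2: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = kernel * kernel * in_channels
        self.kernel = kernel
        self.activation = activation
        self.l2 = l2
        self.params = {
            "W": _init_weight((kernel, kernel, in_channels, out_channels), fan_in, out_channels, "he_uniform", rng),
            "b": np.zeros(out_channels),
        }

    def forward(self, x, training, rng):
        k = self.kernel
        n, h, w, _ = x.shape
        ho, wo = h - k + 1, w - k + 1
        if ho < 1 or wo < 1:
            raise ValueError(f"spatial dims {h}x{w} smaller than kernel {k}")
        self._x = x
        self._shape_out = (n, ho, wo)
        z = np.tile(self.params["b"], (n, ho, wo, 1))
        for di in range(k):
            for dj in range(k):
                z += x[:, di : di + ho, dj : dj + wo, :] @ self.params["W"][di, dj]
        if self.activation == "relu":
            self._z = z
            return np.maximum(z, 0.0)
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * (self._z > 0)
        k = self.kernel
        n, ho, wo = self._shape_out
        x = self._x
        dW = np.empty_like(self.params["W"])
        dx = np.zeros_like(x)
        gflat = grad.reshape(-1, grad.shape[-1])
        for di in range(k):
            for dj in range(k):
                window = x[:, di : di + ho, dj : dj + wo, :].reshape(-1, x.shape[-1])
                dW[di, dj] = window.T @ gflat
                dx[:, di : di + ho, dj : dj + wo, :] += grad @ self.params["W"][di, dj].T
        self.grads["W"] = dW + 2.0 * self.l2 * self.params["W"]
        self.grads["b"] = gflat.sum(axis=0)
        return dx


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; odd margins are dropped."""

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        if ho < 1 or wo < 1:
            raise ValueError(f"spatial dims {h}x{w} too small for 2x2 pooling")
        self._in_shape = x.shape
        xr = (
            x[:, : ho * 2, : wo * 2, :]
            .reshape(n, ho, 2, wo, 2, c)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, ho, wo, 4, c)
        )
        self._idx = xr.argmax(axis=3)
        return np.take_along_axis(xr, self._idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]

    def backward(self, grad):
        n, h, w, c = self._in_shape
        ho, wo = h // 2, w // 2
        scattered = np.zeros((n, ho, wo, 4, c))
        np.put_along_axis(scattered, self._idx[:, :, :, None, :], grad[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, : ho * 2, : wo * 2, :] = (
            scattered.reshape(n, ho, wo, 2, 2, c).transpose(0, 1, 3, 2, 4, 5).reshape(n, ho * 2, wo * 2, c)
        )
        return dx


class GlobalAveragePool(Layer):
    """NHWC feature map -> per-channel mean (the feature tap point)."""

    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._in_shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w), self._in_shape).copy()


class BatchNorm(Layer):
    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._xhat = (x - mean) / np.sqrt(var + self.eps)
        self._istd = 1.0 / np.sqrt(var + self.eps)
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        n = grad.shape[0]
        xhat, istd = self._xhat, self._istd
        self.grads["gamma"] = (grad * xhat).sum(axis=0)
        self.grads["beta"] = grad.sum(axis=0)
        g = grad * self.params["gamma"]
        return istd * (g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0)) if n > 1 else g * istd


class Dropout(Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p <= 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Softmax(Layer):
    """Softmax as a genuine layer (used on aggregation-network inputs)."""

    def forward(self, x, training, rng):
        self._s = softmax(x, axis=-1)
        return self._s

    def backward(self, grad):
        s = self._s
        return s * (grad - (grad * s).sum(axis=-1, keepdims=True))


class Sequential:
    """A feed-forward stack trained with Adam and cross-entropy.

    ``loss`` is ``"categorical_crossentropy"`` (final layer emits logits,
    softmax applied internally) or ``"binary_crossentropy"`` (final layer
    emits one logit, sigmoid applied internally).
    """

    def __init__(self, layers: Sequence[Layer], loss: str = "categorical_crossentropy") -> None:
        if loss not in ("categorical_crossentropy", "binary_crossentropy"):
            raise ValueError(f"unknown loss {loss!r}")
        self.layers = list(layers)
        self.loss = loss

    # --- forward ------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        rng = rng or np.random.default_rng(0)
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        logits = self.forward(x, training=False)
        if self.loss == "binary_crossentropy":
            return sigmoid(logits)
        return softmax(logits, axis=-1)

    # --- loss/metric --------------------------------------------------
    def _loss_and_grad(self, logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
        n = logits.shape[0]
        if self.loss == "binary_crossentropy":
            p = sigmoid(logits)
            eps = 1e-12
            loss = -np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps))
            return float(loss), (p - y) / n
        p = softmax(logits, axis=-1)
        loss = -np.mean(np.sum(y * np.log(p + 1e-12), axis=-1))
        return float(loss), (p - y) / n

    def _accuracy(self, x: np.ndarray, y: np.ndarray) -> float:
        p = self.predict_proba(x)
        if self.loss == "binary_crossentropy":
            return float(np.mean((p > 0.5).astype(int) == y))
        return float(np.mean(p.argmax(axis=-1) == y.argmax(axis=-1)))

    # --- parameter plumbing -------------------------------------------
    def _snapshot(self) -> list[dict[str, np.ndarray]]:
        state = []
        for layer in self.layers:
            entry = {"params": copy.deepcopy(layer.params)}
            if isinstance(layer, BatchNorm):
                entry["running"] = (layer.running_mean.copy(), layer.running_var.copy())
            state.append(entry)
        return state

    def _restore(self, snap: list[dict]) -> None:
        for layer, entry in zip(self.layers, snap):
            layer.params = copy.deepcopy(entry["params"])
            if "running" in entry:
                layer.running_mean, layer.running_var = (a.copy() for a in entry["running"])

    def finalize_batch_stats(self, x: np.ndarray) -> None:
        """Replace batch-norm running statistics with exact full-set moments.

        Per-batch exponential averages lag the shifting pre-normalization
        distribution during training, so inference-mode outputs can diverge
        badly from training-mode fits on small datasets; one exact pass
        removes the mismatch deterministically.
        """
        rng = np.random.default_rng(0)
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean = x.mean(axis=0)
                layer.running_var = x.var(axis=0)
            x = layer.forward(x, False, rng)

    # --- training -----------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        cfg: TrainConfig,
        validation: tuple[np.ndarray, np.ndarray] | None = None,
        epoch_data_fn=None,
    ) -> pd.DataFrame:
        """Train with Adam; returns a per-epoch history table.

        ``epoch_data_fn(epoch, rng) -> (x, y)`` optionally supplies fresh
        (e.g. augmented) training data each epoch; the given ``x, y`` are
        then only the epoch-0 default.
        """
        rng = np.random.default_rng(cfg.seed)
        adam_m: dict[tuple[int, str], np.ndarray] = {}
        adam_v: dict[tuple[int, str], np.ndarray] = {}
        t = 0
        lr = cfg.lr0
        decay = cfg.effective_decay()
        history = []
        best_val = -np.inf
        best_snap = self._snapshot()
        stall = 0
        for epoch in range(cfg.max_epochs):
            if epoch_data_fn is not None:
                x, y = epoch_data_fn(epoch, rng)
            order = rng.permutation(x.shape[0])
            epoch_loss = 0.0
            for start in range(0, len(order), cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = self.forward(x[idx], training=True, rng=rng)
                loss, grad = self._loss_and_grad(logits, y[idx])
                epoch_loss += loss * len(idx)
                for layer in reversed(self.layers):
                    grad = layer.backward(grad)
                t += 1
                for li, layer in enumerate(self.layers):
                    for name, g in layer.grads.items():
                        key = (li, name)
                        m = adam_m.setdefault(key, np.zeros_like(g))
                        v = adam_v.setdefault(key, np.zeros_like(g))
                        m += (1 - cfg.adam_beta1) * (g - m)
                        v += (1 - cfg.adam_beta2) * (g * g - v)
                        mhat = m / (1 - cfg.adam_beta1**t)
                        vhat = v / (1 - cfg.adam_beta2**t)
                        layer.params[name] -= lr * mhat / (np.sqrt(vhat) + 1e-8)
            self.finalize_batch_stats(x)
            row = {
                "epoch": epoch,
                "lr": lr,
                "train_loss": epoch_loss / len(order),
                "train_acc": self._accuracy(x, y),
            }
            if validation is not None:
                xv, yv = validation
                logits_v = self.forward(xv, training=False)
                row["val_loss"] = self._loss_and_grad(logits_v, yv)[0]
                row["val_acc"] = self._accuracy(xv, yv)
                if row["val_acc"] > best_val + cfg.early_stop_tol:
                    best_val = row["val_acc"]
                    best_snap = self._snapshot()
                    stall = 0
                else:
                    stall += 1
            history.append(row)
            lr = lr / (1.0 + decay)
            if validation is not None and stall >= cfg.early_stop_patience:
                break
        if validation is not None:
            self._restore(best_snap)
        return pd.DataFrame(history)
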