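"""A small, fully deterministic 1D convolutional network in NumPy.

Architecture (fixed topology, configurable sizes):

    conv1d(f1, ReLU) -> conv1d(f2, ReLU) -> maxpool -> dropout
    -> dense -> softmax(C)

trained with categorical cross-entropy  L = -sum_i y_i log(p_i),
the Adam optimizer (initial learning rate 0.001) and a reduce-on-plateau
schedule on the validation loss.  The weights with the best validation loss
are retained.  All randomness (init, batch shuffling, dropout masks) flows
from a single seed, so training is bit-reproducible on CPU.

The implementation is intentionally minimal: valid (unpadded) convolutions
via stride tricks, inverted dropout, max-subtracted softmax and a 1e-12
floor inside the log to avoid -inf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import DivergenceError, ParameterError

_LOG_FLOOR = 1e-12


@dataclass
class CNNConfig:
    """Hyperparameters; defaults are the package's standard training setup."""

    f1: int = 32                 # filters, first conv layer
    f2: int = 64                 # filters, second conv layer
    kernel_size: int = 3
    pool_size: int = 2
    dropout: float = 0.3
    learning_rate: float = 0.001  # Adam initial learning rate
    scheduler_factor: float = 0.5
    scheduler_patience: int = 5
    min_lr: float = 1e-5
    epochs: int = 60
    batch_size: int = 32
    n_classes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ParameterError("learning rate must be > 0")
        if not 0 <= self.dropout < 1:
            raise ParameterError("dropout must lie in [0, 1)")
        if self.kernel_size < 1 or self.pool_size < 1:
            raise ParameterError("kernel and pool sizes must be >= 1")


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean categorical cross-entropy -sum_i y_i log(p_i) over samples."""
    p = np.clip(probabilities[np.arange(labels.size), labels], _LOG_FLOOR, None)
    return float(-np.mean(np.log(p)))


def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    # x: (n, c_in, L); w: (f, c_in, k) -> (n, f, L-k+1)
    windows = np.lib.stride_tricks.sliding_window_view(x, w.shape[2], axis=2)
    return np.einsum("ncwk,fck->nfw", windows, w, optimize=True) + b[None, :, None]


def _conv_backward(x: np.ndarray, w: np.ndarray, dz: np.ndarray):
    k = w.shape[2]
    windows = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)
    dw = np.einsum("nfw,ncwk->fck", dz, windows, optimize=True)
    db = dz.sum(axis=(0, 2))
    pad = np.pad(dz, ((0, 0), (0, 0), (k - 1, k - 1)))
    pad_windows = np.lib.stride_tricks.sliding_window_view(pad, k, axis=2)
    dx = np.einsum("nftj,fcj->nct", pad_windows, w[:, :, ::-1], optimize=True)
    return dx, dw, db


class CNN1D:
    """Two-conv-layer 1D CNN classifier over fixed-length feature sequences."""

    def __init__(self, input_length: int, config: CNNConfig):
        c = config
        if input_length < c.kernel_size:
            raise ParameterError(
                f"sequence length {input_length} is shorter than kernel size {c.kernel_size}"
            )
        self.config = c
        self.input_length = input_length
        w1_len = input_length - c.kernel_size + 1
        w2_len = w1_len - c.kernel_size + 1
        if w2_len < 1:
            raise ParameterError("sequence too short for two valid convolutions")
        self.pooled_len = max(w2_len // c.pool_size, 1)
        self._pool_eff = c.pool_size if w2_len >= c.pool_size else 1
        rng = np.random.default_rng(c.seed)
        k = c.kernel_size

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        self.params = {
            "w1": he((c.f1, 1, k), k),
            "b1": np.zeros(c.f1),
            "w2": he((c.f2, c.f1, k), c.f1 * k),
            "b2": np.zeros(c.f2),
            "wd": he((c.f2 * self.pooled_len, c.n_classes), c.f2 * self.pooled_len),
            "bd": np.zeros(c.n_classes),
        }
        self._rng = rng
        self._adam_m = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_v = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------- forward
    def _forward(self, x: np.ndarray, train: bool = False):
        p = self.params
        c = self.config
        x3 = x[:, None, :]
        z1 = _conv_forward(x3, p["w1"], p["b1"])
        a1 = np.maximum(z1, 0.0)
        z2 = _conv_forward(a1, p["w2"], p["b2"])
        a2 = np.maximum(z2, 0.0)
        pool = self._pool_eff
        trimmed = a2[:, :, : self.pooled_len * pool]
        blocks = trimmed.reshape(a2.shape[0], c.f2, self.pooled_len, pool)
        arg = blocks.argmax(axis=3)
        pooled = np.take_along_axis(blocks, arg[..., None], axis=3)[..., 0]
        if train and c.dropout > 0:
            mask = (self._rng.random(pooled.shape) >= c.dropout) / (1.0 - c.dropout)
            dropped = pooled * mask
        else:
            mask = None
            dropped = pooled
        flat = dropped.reshape(x.shape[0], -1)
        logits = flat @ p["wd"] + p["bd"]
        proba = softmax(logits)
        cache = (x3, z1, a1, z2, a2, blocks, arg, mask, flat)
        return proba, cache

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        proba, _ = self._forward(np.asarray(x, dtype=float), train=False)
        return proba

    # ------------------------------------------------------------ backward
    def _backward(self, proba: np.ndarray, labels: np.ndarray, cache):
        p = self.params
        c = self.config
        x3, z1, a1, z2, a2, blocks, arg, mask, flat = cache
        n = labels.size
        dlogits = proba.copy()
        dlogits[np.arange(n), labels] -= 1.0
        dlogits /= n
        grads = {
            "wd": flat.T @ dlogits,
            "bd": dlogits.sum(axis=0),
        }
        dflat = dlogits @ p["wd"].T
        ddropped = dflat.reshape(n, c.f2, self.pooled_len)
        dpooled = ddropped * mask if mask is not None else ddropped
        dblocks = np.zeros_like(blocks)
        np.put_along_axis(dblocks, arg[..., None], dpooled[..., None], axis=3)
        da2 = np.zeros_like(a2)
        pool = self._pool_eff
        da2[:, :, : self.pooled_len * pool] = dblocks.reshape(
            n, c.f2, self.pooled_len * pool
        )
        dz2 = da2 * (z2 > 0)
        da1, grads["w2"], grads["b2"] = _conv_backward(a1, p["w2"], dz2)
        dz1 = da1 * (z1 > 0)
        _, grads["w1"], grads["b1"] = _conv_backward(x3, p["w1"], dz1)
        return grads

    def _adam_step(self, grads: dict, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for key, g in grads.items():
            m = self._adam_m[key] = beta1 * self._adam_m[key] + (1 - beta1) * g
            v = self._adam_v[key] = beta2 * self._adam_v[key] + (1 - beta2) * g * g
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            self.params[key] -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # ------------------------------------------------------------ training
    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: Optional[np.ndarray] = None,
        y_val: Optional[np.ndarray] = None,
    ) -> "TrainingHistory":
        c = self.config
        x_train = np.asarray(x_train, dtype=float)
        y_train = np.asarray(y_train, dtype=int)
        have_val = x_val is not None and len(x_val) > 0
        if have_val:
            x_val = np.asarray(x_val, dtype=float)
            y_val = np.asarray(y_val, dtype=int)
        history = TrainingHistory()
        lr = c.learning_rate
        best_val = np.inf
        best_params = {k: v.copy() for k, v in self.params.items()}
        stall = 0
        n = x_train.shape[0]
        for epoch in range(c.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, c.batch_size):
                idx = order[start : start + c.batch_size]
                proba, cache = self._forward(x_train[idx], train=True)
                grads = self._backward(proba, y_train[idx], cache)
                self._adam_step(grads, lr)
            train_proba = self.predict_proba(x_train)
            train_loss = cross_entropy(train_proba, y_train)
            if not np.isfinite(train_loss):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            train_acc = float((train_proba.argmax(axis=1) == y_train).mean())
            if have_val:
                val_proba = self.predict_proba(x_val)
                val_loss = cross_entropy(val_proba, y_val)
                val_acc = float((val_proba.argmax(axis=1) == y_val).mean())
            else:
                val_loss, val_acc = train_loss, train_acc
            history.append(epoch, train_loss, train_acc, val_loss, val_acc, lr)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in self.params.items()}
                stall = 0
            else:
                stall += 1
                if stall > c.scheduler_patience:
                    lr = max(lr * c.scheduler_factor, c.min_lr)
                    stall = 0
        self.params = best_params
        return history


@dataclass
class TrainingHistory:
    epoch: list = field(default_factory=list)
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)

    def append(self, epoch, tl, ta, vl, va, lr):
        self.epoch.append(epoch)
        self.train_loss.append(tl)
        self.train_accuracy.append(ta)
        self.val_loss.append(vl)
        self.val_accuracy.append(va)
        self.learning_rate.append(lr)
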