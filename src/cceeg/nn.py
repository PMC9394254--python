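"""Minimal NumPy layer engine used to build the C-c CNN.

The architecture only ever carries a single feature map after its first
convolution (the branch-initial kernel spans the full channel axis and
collapses it), so every layer here works on plain ``(batch, length)``
arrays; only :class:`ChannelCollapseConv` accepts ``(batch, channels,
length)`` input.  Each layer implements ``forward`` and ``backward``;
parameter gradients accumulate into ``Param.grad`` (callers zero them
between steps), which lets a layer be shared between branches — its
gradient is then the sum of the branch contributions.

Conventions: valid (unpadded) cross-correlation; max pooling with window 2,
stride 2, keeping a trailing partial window; batch normalization per feature
map (statistics over batch and length) with running statistics for
inference; inverted dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "ChannelCollapseConv",
    "Conv1",
    "BatchNorm",
    "ReLU",
    "MaxPoolHalf",
    "Dropout",
    "Dense",
    "Sequential",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


@dataclass
class Param:
    """A trainable array with its accumulated gradient."""

    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class ChannelCollapseConv(Layer):
    """Full-height convolution: (B, C, L) -> (B, L - width + 1).

    One kernel per input channel, summed into a single output map with a
    shared bias — the ``C x 1 x width`` kernel of the branch tables.
    """

    def __init__(self, n_channels: int, width: int, rng: np.random.Generator):
        fan_in = n_channels * width
        self.w = Param(rng.standard_normal((n_channels, width)) * np.sqrt(2.0 / fan_in))
        self.b = Param(np.zeros(()))
        self.width = width
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        lout = x.shape[2] - self.width + 1
        out = np.full((x.shape[0], lout), self.b.value, dtype=np.float64)
        for k in range(self.width):
            out += np.tensordot(x[:, :, k : k + lout], self.w.value[:, k], axes=([1], [0]))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        lout = grad.shape[1]
        dx = np.zeros_like(x)
        for k in range(self.width):
            self.w.grad[:, k] += np.tensordot(grad, x[:, :, k : k + lout], axes=([0, 1], [0, 2]))
            dx[:, :, k : k + lout] += grad[:, None, :] * self.w.value[:, k][None, :, None]
        self.b.grad += grad.sum()
        return dx

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Conv1(Layer):
    """Single-map 1-D convolution: (B, L) -> (B, L - width + 1)."""

    def __init__(self, width: int, rng: np.random.Generator):
        self.w = Param(rng.standard_normal(width) * np.sqrt(2.0 / width))
        self.b = Param(np.zeros(()))
        self.width = width
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        lout = x.shape[1] - self.width + 1
        out = np.full((x.shape[0], lout), self.b.value, dtype=np.float64)
        for k in range(self.width):
            out += x[:, k : k + lout] * self.w.value[k]
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._x
        lout = grad.shape[1]
        dx = np.zeros_like(x)
        for k in range(self.width):
            self.w.grad[k] += np.sum(grad * x[:, k : k + lout])
            dx[:, k : k + lout] += grad * self.w.value[k]
        self.b.grad += grad.sum()
        return dx

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BatchNorm(Layer):
    """Per-feature-map batch normalization over batch and length."""

    def __init__(self, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(()))
        self.beta = Param(np.zeros(()))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = 0.0
        self.running_var = 1.0
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean, var = x.mean(), x.var()
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_sd
        self._cache = (xhat, inv_sd, training)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_sd, training = self._cache
        self.gamma.grad += np.sum(grad * xhat)
        self.beta.grad += grad.sum()
        g = grad * self.gamma.value
        if not training:
            return g * inv_sd
        return inv_sd * (g - g.mean() - xhat * np.mean(g * xhat))

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPoolHalf(Layer):
    """Window-2, stride-2 max pooling keeping a trailing partial window."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, length = x.shape
        self._in_length = length
        padded = x
        if length % 2:
            padded = np.concatenate([x, np.full((b, 1), -np.inf)], axis=1)
        blocks = padded.reshape(b, -1, 2)
        self._argmax = blocks.argmax(axis=2)
        return blocks.max(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, lout = grad.shape
        dpadded = np.zeros((b, lout, 2))
        rows = np.arange(b)[:, None]
        cols = np.arange(lout)[None, :]
        dpadded[rows, cols, self._argmax] = grad
        return dpadded.reshape(b, 2 * lout)[:, : self._in_length]


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = 1.0
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = Param(rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]


class Adam:
    """Adam with standard bias correction."""

    def __init__(self, params: Sequence[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * p.grad
            v[...] = self.beta2 * v + (1 - self.beta2) * p.grad**2
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.sum(onehot * np.log(probs + 1e-12)) / n)
    return loss, (probs - onehot) / n
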