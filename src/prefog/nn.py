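"""Minimal 1D convolutional network engine with full introspection.

A small, self-contained numpy implementation of the layer types the gait
classifier needs: 1D convolution (same padding), ReLU, local max pooling,
global average pooling, dropout and a dense softmax head. Every layer exposes
its weights and, on a recorded forward pass, its input activations — the
introspection that layer-wise relevance propagation requires.

Shapes follow the (time, channels) convention for a single example and
(batch, time, channels) for batches.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


class Layer:
    params: tuple = ()

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


def _im2col(x, k):
    """(N, T, C) -> (N, T-k+1, k*C) sliding windows."""
    n, t, c = x.shape
    out_t = t - k + 1
    s0, s1, s2 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x, shape=(n, out_t, k, c), strides=(s0, s1, s1, s2), writeable=False
    )
    return windows.reshape(n, out_t, k * c)


class Conv1D(Layer):
    """Same-padded 1D convolution; weights (filters, kernel, in_channels)."""

    def __init__(self, in_channels: int, filters: int, kernel: int, rng):
        if kernel % 2 != 1:
            raise ValueError("kernel length must be odd")
        self.kernel = kernel
        self.in_channels = in_channels
        self.filters = filters
        scale = np.sqrt(2.0 / (kernel * in_channels))  # He initialization
        self.W = rng.normal(0.0, scale, size=(filters, kernel, in_channels))
        self.b = np.zeros(filters)
        self.params = ("W", "b")

    @property
    def pad(self):
        return (self.kernel - 1) // 2

    def forward(self, x, train: bool = False):
        if x.shape[1] < self.kernel:
            raise ValueError(
                f"input length {x.shape[1]} shorter than kernel {self.kernel}"
            )
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        cols = np.ascontiguousarray(_im2col(xp, self.kernel))  # (N, T, k*C)
        self._cols = cols
        self._x_shape = x.shape
        n, t, kc = cols.shape
        out = cols.reshape(n * t, kc) @ self.W.reshape(self.filters, -1).T
        return out.reshape(n, t, self.filters) + self.b

    def backward(self, grad):
        # grad: (N, T, F)
        n, t, f = grad.shape
        Wmat = self.W.reshape(f, -1)
        grad2 = np.ascontiguousarray(grad).reshape(n * t, f)
        cols2 = self._cols.reshape(n * t, -1)
        self.gW = (grad2.T @ cols2).reshape(self.W.shape)
        self.gb = grad.sum(axis=(0, 1))
        gcols = (grad2 @ Wmat).reshape(n, t, self.kernel, self.in_channels)
        gx = np.zeros((n, t + 2 * self.pad, self.in_channels))
        for j in range(self.kernel):
            gx[:, j : j + t] += gcols[:, :, j]
        return gx[:, self.pad : self.pad + self._x_shape[1]]

    def max_norm_(self, cap: float):
        norms = np.sqrt((self.W.reshape(self.filters, -1) ** 2).sum(axis=1))
        factor = np.minimum(1.0, cap / np.maximum(norms, 1e-12))
        self.W *= factor[:, None, None]


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along time; trailing remainder dropped."""

    def __init__(self, width: int):
        if width < 1:
            raise ValueError("pool width must be >= 1")
        self.width = width

    def forward(self, x, train: bool = False):
        n, t, c = x.shape
        out_t = t // self.width
        self._in_shape = x.shape
        xw = x[:, : out_t * self.width].reshape(n, out_t, self.width, c)
        self._windows = xw
        out = xw.max(axis=2)
        self._argmask = xw == out[:, :, None, :]
        return out

    def backward(self, grad):
        n, t, c = self._in_shape
        counts = self._argmask.sum(axis=2, keepdims=True)
        g = self._argmask * (grad[:, :, None, :] / counts)
        out = np.zeros((n, t, c))
        out_t = g.shape[1]
        out[:, : out_t * self.width] = g.reshape(n, out_t * self.width, c)
        return out


class GlobalAvgPool(Layer):
    def forward(self, x, train: bool = False):
        self._t = x.shape[1]
        return x.mean(axis=1)

    def backward(self, grad):
        return np.repeat(grad[:, None, :], self._t, axis=1) / self._t


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool = False):
        if train and self.rate > 0.0:
            self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        else:
            self._mask = np.ones_like(x)
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng):
        scale = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = ("W", "b")

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T

    def max_norm_(self, cap: float):
        norms = np.sqrt((self.W**2).sum(axis=0))
        factor = np.minimum(1.0, cap / np.maximum(norms, 1e-12))
        self.W *= factor[None, :]


class Softmax(Layer):
    def forward(self, x, train: bool = False):
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def backward(self, grad):  # handled jointly with the cross-entropy loss
        return grad


class Network:
    """Ordered layer stack with recorded activations.

    ``forward(..., record=True)`` stores each layer's input in
    ``self.recorded`` as ``(layer, input_activation)`` pairs, enabling
    relevance propagation without re-running layers.
    """

    def __init__(self, layers):
        self.layers = list(layers)
        self.recorded = None

    def forward(self, x, train: bool = False, record: bool = False):
        x = np.asarray(x, dtype=float)
        rec = [] if record else None
        for layer in self.layers:
            if record:
                rec.append((layer, x))
            x = layer.forward(x, train=train)
        if record:
            self.recorded = rec
        return x

    def logits(self, x):
        """Pre-softmax scores."""
        x = np.asarray(x, dtype=float)
        for layer in self.layers:
            if isinstance(layer, Softmax):
                return x
            x = layer.forward(x, train=False)
        raise ValueError("network has no softmax head")

    def parametric_layers(self):
        return [l for l in self.layers if l.params]

    def n_parameters(self) -> int:
        return sum(
            getattr(l, p).size for l in self.parametric_layers() for p in l.params
        )

    def apply_max_norm(self, cap: float):
        for layer in self.layers:
            if hasattr(layer, "max_norm_"):
                layer.max_norm_(cap)

    def weight_norms(self):
        norms = []
        for layer in self.parametric_layers():
            W = layer.W
            if W.ndim == 3:
                norms.extend(np.sqrt((W.reshape(W.shape[0], -1) ** 2).sum(axis=1)))
            else:
                norms.extend(np.sqrt((W**2).sum(axis=0)))
        return np.array(norms)

    # -- portable checkpoint: architecture JSON + flat weight arrays ---------

    def to_checkpoint(self) -> dict:
        arch, weights = [], {}
        for i, layer in enumerate(self.layers):
            entry = {"type": type(layer).__name__}
            if isinstance(layer, Conv1D):
                entry.update(in_channels=layer.in_channels, filters=layer.filters,
                             kernel=layer.kernel)
            elif isinstance(layer, MaxPool1D):
                entry.update(width=layer.width)
            elif isinstance(layer, Dropout):
                entry.update(rate=layer.rate)
            elif isinstance(layer, Dense):
                entry.update(n_in=layer.W.shape[0], n_out=layer.W.shape[1])
            for p in layer.params:
                weights[f"layer{i}_{p}"] = getattr(layer, p).ravel().tolist()
            arch.append(entry)
        return {"architecture": arch, "weights": weights}

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_checkpoint()))

    @classmethod
    def from_checkpoint(cls, payload: dict) -> "Network":
        rng = np.random.default_rng(0)
        layers = []
        for i, entry in enumerate(payload["architecture"]):
            kind = entry["type"]
            if kind == "Conv1D":
                layer = Conv1D(entry["in_channels"], entry["filters"], entry["kernel"], rng)
            elif kind == "ReLU":
                layer = ReLU()
            elif kind == "MaxPool1D":
                layer = MaxPool1D(entry["width"])
            elif kind == "GlobalAvgPool":
                layer = GlobalAvgPool()
            elif kind == "Dropout":
                layer = Dropout(entry["rate"], rng)
            elif kind == "Dense":
                layer = Dense(entry["n_in"], entry["n_out"], rng)
            elif kind == "Softmax":
                layer = Softmax()
            else:
                raise ValueError(f"unknown layer type {kind!r}")
            for p in layer.params:
                flat = np.array(payload["weights"][f"layer{i}_{p}"])
                setattr(layer, p, flat.reshape(getattr(layer, p).shape))
            layers.append(layer)
        return cls(layers)

    @classmethod
    def load(cls, path) -> "Network":
        return cls.from_checkpoint(json.loads(Path(path).read_text()))


class Adam:
    """Adam optimizer over a network's parametric layers."""

    def __init__(self, net: Network, beta1=0.9, beta2=0.999, eps=1e-8):
        self.net = net
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {}
        self.v = {}
        for i, layer in enumerate(net.layers):
            for p in layer.params:
                self.m[(i, p)] = np.zeros_like(getattr(layer, p))
                self.v[(i, p)] = np.zeros_like(getattr(layer, p))

    def step(self, lr: float):
        self.t += 1
        for i, layer in enumerate(self.net.layers):
            for p in layer.params:
                g = getattr(layer, "g" + p)
                key = (i, p)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g**2
                mhat = self.m[key] / (1 - self.beta1**self.t)
                vhat = self.v[key] / (1 - self.beta2**self.t)
                new = getattr(layer, p) - lr * mhat / (np.sqrt(vhat) + self.eps)
                setattr(layer, p, new)
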