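"""Primitive layers operating on channel-last (N, H, W, C) float arrays.

Channel-last keeps im2col patch extraction and the conv matmuls contiguous,
which is what makes a pure numpy training loop fast enough for CPU use.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

from segmatch.errors import GeometryError


class Layer:
    """Base class: stateful forward cache, explicit backward."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray, want_param_grads: bool = True) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> List[Tuple[str, np.ndarray]]:
        return []

    def grads(self) -> Dict[str, np.ndarray]:
        return {}

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g.fill(0.0)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(N, H, W, C) -> (N*Ho*Wo, k*k*C) patch matrix."""
    n, h, w, c = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (n, ho, wo, k, k, c),
        (s[0], s[1] * stride, s[2] * stride, s[1], s[2], s[3]))
    return view.reshape(n * ho * wo, k * k * c), ho, wo


def _col2im(dcols: np.ndarray, xshape, k: int, stride: int, pad: int) -> np.ndarray:
    n, h, w, c = xshape
    ho = (h + 2 * pad - k) // stride + 1
    wo = (w + 2 * pad - k) // stride + 1
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c), dtype=dcols.dtype)
    d6 = dcols.reshape(n, ho, wo, k, k, c)
    for ki in range(k):
        for kj in range(k):
            dxp[:, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride, :] \
                += d6[:, :, :, ki, kj, :]
    if pad:
        return dxp[:, pad:pad + h, pad:pad + w, :]
    return dxp


class Conv2d(Layer):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(cout, fan_in)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.cin:
            raise GeometryError(f"expected {self.cin} channels, got {c}")
        if self.k == 1 and self.stride == 1:
            cols, ho, wo = x.reshape(-1, c), h, w
        else:
            cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
            cols = np.ascontiguousarray(cols)
        y = cols @ self.W.T + self.b
        self._cache = (cols, x.shape, ho, wo)
        return y.reshape(n, ho, wo, self.cout)

    def backward(self, dy: np.ndarray, want_param_grads: bool = True) -> np.ndarray:
        cols, xshape, ho, wo = self._cache
        dyf = dy.reshape(-1, self.cout)
        if want_param_grads:
            self.dW += dyf.T @ cols
            self.db += dyf.sum(axis=0)
        dcols = dyf @ self.W
        if self.k == 1 and self.stride == 1:
            return dcols.reshape(xshape)
        return _col2im(dcols, xshape, self.k, self.stride, self.pad)

    def parameters(self):
        return [("W", self.W), ("b", self.b)]

    def grads(self):
        return {"W": self.dW, "b": self.db}


class BatchNorm2d(Layer):
    """Per-channel normalization: batch statistics in training mode,
    running statistics in evaluation/attack mode."""

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32) -> None:
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps
        self.freeze_stats = False  # batch stats without running updates
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = (0, 1, 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            if not self.freeze_stats:
                self.running_mean += self.momentum * (mean - self.running_mean)
                self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean
            var = self.running_var
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray, want_param_grads: bool = True) -> np.ndarray:
        xhat, inv_std, train, xshape = self._cache
        axes = (0, 1, 2)
        if want_param_grads:
            self.dgamma += (dy * xhat).sum(axis=axes)
            self.dbeta += dy.sum(axis=axes)
        if not train:
            return dy * (self.gamma * inv_std)
        m = xshape[0] * xshape[1] * xshape[2]
        dxhat = dy * self.gamma
        term = (m * dxhat
                - dxhat.sum(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))
        return term * inv_std / m

    def parameters(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return [("running_mean", self.running_mean), ("running_var", self.running_var)]


class GroupNorm2d(Layer):
    """Per-image, per-channel-group normalization.

    Identical in training and evaluation mode, so the weak, strong and
    attack passes all see the same deterministic function of their input —
    no batch coupling and no running statistics.
    """

    def __init__(self, channels: int, groups: int | None = None,
                 eps: float = 1e-5, dtype=np.float32) -> None:
        if groups is None:
            groups = 4 if channels % 4 == 0 else 1
        if channels % groups:
            raise GeometryError(f"{channels} channels not divisible into "
                                f"{groups} groups")
        self.channels = channels
        self.groups = groups
        self.eps = eps
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache = None

    def _grouped(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        return x.reshape(n, h, w, self.groups, c // self.groups)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        g = self._grouped(x)
        axes = (1, 2, 4)
        mean = g.mean(axis=axes, keepdims=True)
        var = g.var(axis=axes, keepdims=True)
        inv_std = (1.0 / np.sqrt(var + self.eps)).astype(x.dtype)
        xhat = ((g - mean) * inv_std).reshape(x.shape)
        self._cache = (xhat, inv_std, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray, want_param_grads: bool = True) -> np.ndarray:
        xhat, inv_std, xshape = self._cache
        if want_param_grads:
            self.dgamma += (dy * xhat).sum(axis=(0, 1, 2))
            self.dbeta += dy.sum(axis=(0, 1, 2))
        axes = (1, 2, 4)
        n, h, w, c = xshape
        m = h * w * (c // self.groups)
        dxhat = self._grouped(dy * self.gamma)
        xhat_g = self._grouped(xhat)
        term = (m * dxhat
                - dxhat.sum(axis=axes, keepdims=True)
                - xhat_g * (dxhat * xhat_g).sum(axis=axes, keepdims=True))
        return (term * inv_std / m).reshape(xshape)

    def parameters(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray, want_param_grads: bool = True) -> np.ndarray:
        return dy * self._mask


class UpsampleNearest2x(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray, want_param_grads: bool = True) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray, want_param_grads: bool = True) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy, want_param_grads)
        return dy

    def parameters(self):
        out = []
        for i, layer in enumerate(self.layers):
            out.extend((f"{i}.{name}", p) for name, p in layer.parameters())
        return out

    def grads(self):
        out = {}
        for i, layer in enumerate(self.layers):
            out.update({f"{i}.{name}": g for name, g in layer.grads().items()})
        return out
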