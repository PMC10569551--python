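"""Layer primitives with explicit forward and backward passes.

All tensors are ``float32`` arrays of shape ``(N, C, D, H, W)``.  Each
layer caches what its backward pass needs on ``forward`` and returns the
input gradient from ``backward``; trainable layers expose ``params()``
and accumulate gradients in ``grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv3d",
    "BatchNorm3d",
    "ReLU",
    "Sigmoid",
    "MaxPool3d",
    "UpsampleNearest3d",
    "Adam",
]


class Layer:
    training: bool = True

    def params(self) -> dict:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,D,H,W) zero-padded to 'same', unfolded to (N, D*H*W, C*k^3)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    n, c, d, h, w = x.shape
    # (N, C, D, H, W, k, k, k) -> (N, D*H*W, C*k^3)
    win = win.transpose(0, 2, 3, 4, 1, 5, 6, 7)
    return win.reshape(n, d * h * w, c * k**3)


class Conv3d(Layer):
    """3D convolution, stride 1, zero 'same' padding, odd kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3, rng=None):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd for same-padding")
        self.cin = in_channels
        self.cout = out_channels
        self.k = kernel
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel**3
        # He initialisation for ReLU networks
        self.weight = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel, kernel)).astype(np.float32)
        self.bias = np.zeros(out_channels, dtype=np.float32)
        self.grads = {"weight": np.zeros_like(self.weight), "bias": np.zeros_like(self.bias)}

    def params(self):
        return {"weight": self.weight, "bias": self.bias}

    def forward(self, x):
        self._x_shape = x.shape
        n, c, d, h, w = x.shape
        cols = _im2col(x, self.k)  # (N, DHW, C*k3)
        self._cols = cols
        wmat = self.weight.reshape(self.cout, -1)  # (F, C*k3)
        out = cols @ wmat.T + self.bias  # (N, DHW, F)
        return np.ascontiguousarray(out.transpose(0, 2, 1).reshape(n, self.cout, d, h, w))

    def backward(self, dy):
        n, c, d, h, w = self._x_shape
        dyf = dy.reshape(n, self.cout, -1).transpose(0, 2, 1)  # (N, DHW, F)
        dw = np.einsum("nif,nic->fc", dyf, self._cols, optimize=True)
        self.grads["weight"] += dw.reshape(self.weight.shape)
        self.grads["bias"] += dyf.sum(axis=(0, 1))
        # input gradient = same-padding convolution of dy with the
        # spatially flipped kernel, in/out channels swapped
        wflip = self.weight[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        cols_dy = _im2col(dy, self.k)  # (N, DHW, F*k3)
        dx = cols_dy @ wflip.reshape(self.cin, -1).T  # (N, DHW, Cin)
        self._cols = None
        return np.ascontiguousarray(dx.transpose(0, 2, 1).reshape(n, c, d, h, w))


class BatchNorm3d(Layer):
    """Per-channel batch normalisation over batch and spatial axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.c = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.grads = {"gamma": np.zeros_like(self.gamma), "beta": np.zeros_like(self.beta)}

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def forward(self, x):
        axes = (0, 2, 3, 4)
        if self.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean = self.running_mean
            var = self.running_var
        m = mean.reshape(1, -1, 1, 1, 1)
        v = var.reshape(1, -1, 1, 1, 1)
        self._inv_std = 1.0 / np.sqrt(v + self.eps)
        self._xhat = (x - m) * self._inv_std
        return self.gamma.reshape(1, -1, 1, 1, 1) * self._xhat + self.beta.reshape(1, -1, 1, 1, 1)

    def backward(self, dy):
        axes = (0, 2, 3, 4)
        self.grads["gamma"] += (dy * self._xhat).sum(axis=axes)
        self.grads["beta"] += dy.sum(axis=axes)
        g = self.gamma.reshape(1, -1, 1, 1, 1)
        if not self.training:
            return dy * g * self._inv_std
        nm = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        dxhat = dy * g
        dx = (
            dxhat
            - dxhat.mean(axis=axes, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes, keepdims=True)
        ) * self._inv_std
        return dx


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0)


class Sigmoid(Layer):
    def forward(self, x):
        out = np.empty_like(x)
        np.negative(x, out=out)
        np.exp(out, out=out)
        out += 1.0
        np.reciprocal(out, out=out)
        self._out = out
        return out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2."""

    def forward(self, x):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError("spatial dims must be even for 2x pooling")
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(n, c, d // 2, h // 2, w // 2, 8)
        self._arg = xr.argmax(axis=-1)
        self._in_shape = x.shape
        return xr.max(axis=-1)

    def backward(self, dy):
        n, c, d, h, w = self._in_shape
        out = np.zeros((n, c, d // 2, h // 2, w // 2, 8), dtype=dy.dtype)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        out = out.reshape(n, c, d // 2, h // 2, w // 2, 2, 2, 2)
        out = out.transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return out.reshape(n, c, d, h, w)


class UpsampleNearest3d(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)

    def backward(self, dy):
        n, c, d, h, w = dy.shape
        dr = dy.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        return dr.sum(axis=(3, 5, 7))


class Adam:
    """Adam optimiser over a list of (layer, param-name) entries."""

    def __init__(self, layers, lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.entries = []
        for layer in layers:
            for name in layer.params():
                self.entries.append((layer, name))
        self.lr = lr
        self.b1 = beta1
        self.b2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(layer.params()[name]) for layer, name in self.entries]
        self.v = [np.zeros_like(layer.params()[name]) for layer, name in self.entries]

    def zero_grad(self):
        for layer, name in self.entries:
            layer.grads[name][...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for i, (layer, name) in enumerate(self.entries):
            g = layer.grads[name]
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            layer.params()[name][...] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
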