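"""Minimal CPU neural-network primitives (forward + backprop + Adam).

Everything operates on batched arrays: images are (B, C, H, W), vectors
(B, F).  Convolutions are stride-1, odd-kernel, zero-padded 'same',
implemented by im2col + one BLAS matmul; no layer carries a bias term.
Layers cache what they need during ``forward(..., train=True)`` and release
it after ``backward``.  All computation is deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B, H*W, C*k*k) patch matrix for 'same' zero padding."""
    b, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h * w, c * k * k)


class Layer:
    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv2D(Layer):
    """Stride-1 'same' cross-correlation, no bias."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator, dtype=np.float32):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd")
        std = np.sqrt(2.0 / (c_in * k * k))
        self.w = (rng.normal(0.0, std, size=(c_out, c_in, k, k))).astype(dtype)
        self.k = k
        self.gw: np.ndarray | None = None
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        cols = _im2col(x, self.k)
        out = cols @ self.w.reshape(self.w.shape[0], -1).T
        if train:
            self._x = x
        return out.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        b, c_out, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(b, h * w, c_out)
        cols = _im2col(x, self.k)
        self.gw = (
            np.einsum("bpo,bpc->oc", dflat, cols, optimize=True)
            .reshape(self.w.shape)
            .astype(self.w.dtype)
        )
        # dx = 'same' correlation of dout with the spatially-flipped,
        # channel-swapped kernel (exact for symmetric zero padding).
        wt = np.ascontiguousarray(self.w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        cols_d = _im2col(dout, self.k)
        dx = cols_d @ wt.reshape(wt.shape[0], -1).T
        self._x = None
        return dx.reshape(b, h, w, -1).transpose(0, 3, 1, 2)

    def params(self):
        return {"w": self.w}

    def grads(self):
        return {"w": self.gw}


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2x2(Layer):
    """2x2, stride-2 max pooling; trailing odd rows/cols are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, : h2 * 2, : w2 * 2].reshape(b, c, h2, 2, w2, 2)
        flat = xt.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        dflat = np.zeros((b, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(dflat, self._idx[..., None], dout[..., None], axis=-1)
        dx = np.zeros(self._in_shape, dtype=dout.dtype)
        dx[:, :, : h2 * 2, : w2 * 2] = (
            dflat.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2 * 2, w2 * 2)
        )
        self._idx = None
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer without bias (the 'unbiased neurons')."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        std = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype)
        self.gw: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.gw = (self._x.T @ dout).astype(self.w.dtype)
        self._x = None
        return dout @ self.w.T

    def params(self):
        return {"w": self.w}

    def grads(self):
        return {"w": self.gw}


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_params(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                out.update(layer.named_params(f"{prefix}{i}."))
            else:
                for name, p in layer.params().items():
                    out[f"{prefix}{i}.{name}"] = p
        return out

    def named_grads(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, Sequential):
                out.update(layer.named_grads(f"{prefix}{i}."))
            else:
                for name, g in layer.grads().items():
                    out[f"{prefix}{i}.{name}"] = g
        return out


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dz)."""
    z = z.astype(np.float64)
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / z.shape[0]
    return loss, dz


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            p -= (self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)).astype(p.dtype)
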