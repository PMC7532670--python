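"""Minimal NumPy neural-network layers used by the patch-level classifier.

Implements exactly what the compact backbone needs: stride-1 'same'
convolution via im2col, non-overlapping max pooling, ReLU, a dense head,
weighted binary cross-entropy with logits, and SGD with momentum.  All
operations are deterministic for a fixed RNG.
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,H,W,C) -> (N,H,W,k*k*C) sliding windows, zero-padded 'same'."""
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    n, hp, wp, c = xp.shape
    oh, ow = hp - k + 1, wp - k + 1
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, (n, oh, ow, k, k, c), (s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return view.reshape(n, oh, ow, k * k * c)


def _col2im(dcol: np.ndarray, x_shape, k: int, pad: int) -> np.ndarray:
    """Adjoint of _im2col: scatter-add window gradients back to the input."""
    n, h, w, c = x_shape
    dxp = np.zeros((n, h + 2 * pad, w + 2 * pad, c))
    dcol = dcol.reshape(n, h, w, k, k, c)
    for i in range(k):
        for j in range(k):
            dxp[:, i : i + h, j : j + w, :] += dcol[:, :, :, i, j, :]
    return dxp[:, pad : pad + h, pad : pad + w, :]


class Conv2D:
    """3x3 same-padding stride-1 convolution, He-initialized."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = k * k * c_in
        self.w = rng.normal(0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out))
        self.b = np.zeros(c_out)
        self.k = k
        self.pad = k // 2
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        col = _im2col(x, self.k, self.pad)
        self._cache = (x.shape, col)
        return col @ self.w + self.b

    def backward(self, dout: np.ndarray):
        x_shape, col = self._cache
        n, h, w, _ = dout.shape
        dflat = dout.reshape(-1, dout.shape[-1])
        self.dw = col.reshape(-1, col.shape[-1]).T @ dflat
        self.db = dflat.sum(axis=0)
        dcol = dflat @ self.w.T
        return _col2im(dcol.reshape(n, h, w, -1), x_shape, self.k, self.pad)

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class MaxPool:
    """Non-overlapping p x p max pooling."""

    def __init__(self, p: int):
        self.p = p
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.p
        n, h, w, c = x.shape
        xr = (
            x.reshape(n, h // p, p, w // p, p, c)
            .transpose(0, 1, 3, 5, 2, 4)
            .reshape(n, h // p, w // p, c, p * p)
        )
        idx = xr.argmax(axis=-1)
        self._cache = (x.shape, idx)
        return np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray):
        (n, h, w, c), idx = self._cache
        p = self.p
        dxr = np.zeros((n, h // p, w // p, c, p * p))
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        return (
            dxr.reshape(n, h // p, w // p, c, p, p)
            .transpose(0, 1, 4, 2, 5, 3)
            .reshape(n, h, w, c)
        )


class ReLU:
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = rng.normal(0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        self.b = np.zeros(d_out)

    def forward(self, x):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


def sigmoid(z):
    return np.where(z >= 0, 1 / (1 + np.exp(-np.clip(z, -500, 500))),
                    np.exp(np.clip(z, -500, 500)) / (1 + np.exp(np.clip(z, -500, 500))))


def bce_with_logits(z, y, weight=None):
    """Weighted BCE with logits; returns (mean loss, dL/dz)."""
    z = z.ravel()
    y = y.ravel().astype(float)
    if weight is None:
        weight = np.ones_like(y)
    weight = weight / weight.sum() * len(weight)
    # softplus(z) - y z, numerically stable
    loss = np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))
    dz = weight * (sigmoid(z) - y) / len(y)
    return float((weight * loss).mean()), dz[:, None]


class SGDMomentum:
    def __init__(self, lr: float, momentum: float = 0.9):
        self.lr = lr
        self.momentum = momentum
        self._vel: dict[int, np.ndarray] = {}

    def step(self, layers):
        for li, layer in enumerate(layers):
            if not hasattr(layer, "params"):
                continue
            for pi, (_, value, grad) in enumerate(layer.params()):
                key = (li, pi)
                v = self._vel.get(key)
                if v is None:
                    v = np.zeros_like(value)
                v = self.momentum * v - self.lr * grad
                self._vel[key] = v
                value += v


class TinyCNN:
    """Compact convolutional binary classifier: 2 conv blocks + 1 dense logit.

    conv3x3(3->8) + ReLU + maxpool4, conv3x3(8->16) + ReLU + maxpool4,
    flatten, dense -> 1.  For a 64x64 input the dense layer sees 4*4*16 = 256
    features.
    """

    def __init__(self, input_size: int, seed: int = 0, c1: int = 8, c2: int = 16):
        if input_size % 16 != 0:
            raise ValueError("input_size must be a multiple of 16")
        rng = np.random.default_rng(seed)
        self.input_size = input_size
        self.layers = [
            Conv2D(3, c1, 3, rng),
            ReLU(),
            MaxPool(4),
            Conv2D(c1, c2, 3, rng),
            ReLU(),
            MaxPool(4),
        ]
        d = (input_size // 16) ** 2 * c2
        self.head = Dense(d, 1, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        self._feat_shape = x.shape
        return self.head.forward(x.reshape(x.shape[0], -1))

    def backward(self, dz: np.ndarray) -> None:
        d = self.head.backward(dz).reshape(self._feat_shape)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def predict_logits(self, x: np.ndarray, batch: int = 256) -> np.ndarray:
        out = [self.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
        return np.concatenate(out).ravel()

    @property
    def all_layers(self):
        return self.layers + [self.head]

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for li, layer in enumerate(self.all_layers):
            if hasattr(layer, "w"):
                out[f"layer{li}_w"] = layer.w
                out[f"layer{li}_b"] = layer.b
        return out

    def set_weights(self, d: dict[str, np.ndarray]) -> None:
        for li, layer in enumerate(self.all_layers):
            if hasattr(layer, "w"):
                layer.w = np.array(d[f"layer{li}_w"])
                layer.b = np.array(d[f"layer{li}_b"])
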