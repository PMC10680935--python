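"""Minimal NumPy layer library with hand-derived backward passes.

The field estimator needs only a handful of layer types (3x3x3 same
convolution, instance normalization, leaky ReLU, 2x max pooling,
stride-2 transpose convolution, channel concatenation) plus Adam, so
they are implemented directly on NumPy arrays rather than pulling in a
deep-learning framework.  Convolutions are evaluated as 27 shifted GEMMs,
which keeps peak memory low and lets BLAS do the heavy lifting on a
single CPU.

Activations are channel-first ``(C, D, H, W)`` arrays.  Every layer
caches what its backward pass needs during ``forward`` and releases it
after ``backward``.  All parameters live in :class:`Param` objects so the
optimizer and checkpointing can treat the network as a flat list.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Param",
    "Conv3d",
    "Conv1x1",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "LeakyReLU",
    "MaxPool3d",
    "Adam",
]

_K = 3  # spatial kernel size used throughout


class Param:
    """A trainable array and its accumulated gradient."""

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0

    @property
    def size(self) -> int:
        return self.value.size


def _he_std(fan_in: float, slope: float) -> float:
    return float(np.sqrt(2.0 / (fan_in * (1.0 + slope ** 2))))


class Conv3d:
    """3x3x3 convolution with padding 1 (shape preserving)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 slope: float = 0.01, zero_init: bool = False,
                 dtype=np.float32, name: str = "conv"):
        self.cin, self.cout = cin, cout
        fan_in = cin * _K ** 3
        if zero_init:
            w = np.zeros((cout, cin, _K, _K, _K))
        else:
            w = rng.normal(0.0, _he_std(fan_in, slope),
                           size=(cout, cin, _K, _K, _K))
        self.w = Param(w.astype(dtype), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cin, d, h, w = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        n = d * h * w
        out = np.zeros((self.cout, n), dtype=x.dtype)
        W = self.w.value.reshape(self.cout, self.cin, -1)
        for t, (kd, kh, kw) in enumerate(product(range(_K), repeat=3)):
            sub = xp[:, kd:kd + d, kh:kh + h, kw:kw + w].reshape(cin, n)
            out += W[:, :, t] @ sub
        out += self.b.value[:, None]
        self._cache = xp
        return out.reshape(self.cout, d, h, w)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xp = self._cache
        cout, d, h, w = gy.shape
        n = d * h * w
        g = gy.reshape(cout, n)
        gxp = np.zeros_like(xp)
        W = self.w.value.reshape(self.cout, self.cin, -1)
        gW = np.empty_like(W)
        for t, (kd, kh, kw) in enumerate(product(range(_K), repeat=3)):
            sub = xp[:, kd:kd + d, kh:kh + h, kw:kw + w].reshape(self.cin, n)
            gW[:, :, t] = g @ sub.T
            gxp[:, kd:kd + d, kh:kh + h, kw:kw + w] += (
                W[:, :, t].T @ g).reshape(self.cin, d, h, w)
        self.w.grad += gW.reshape(self.w.value.shape)
        self.b.grad += g.sum(axis=1)
        self._cache = None
        return gxp[:, 1:-1, 1:-1, 1:-1]


class Conv1x1:
    """Pointwise (1x1x1) linear projection across channels."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 slope: float = 0.01, zero_init: bool = False,
                 dtype=np.float32, name: str = "proj"):
        self.cin, self.cout = cin, cout
        if zero_init:
            w = np.zeros((cout, cin))
        else:
            w = rng.normal(0.0, _he_std(cin, slope), size=(cout, cin))
        self.w = Param(w.astype(dtype), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        y = self.w.value @ flat + self.b.value[:, None]
        self._cache = flat
        return y.reshape((self.cout,) + x.shape[1:])

    def backward(self, gy: np.ndarray) -> np.ndarray:
        flat = self._cache
        g = gy.reshape(self.cout, -1)
        self.w.grad += g @ flat.T
        self.b.grad += g.sum(axis=1)
        gx = self.w.value.T @ g
        self._cache = None
        return gx.reshape((self.cin,) + gy.shape[1:])


class ConvTranspose3d:
    """3x3x3 transpose convolution with stride 2, exactly doubling shape.

    Equivalent to the framework convention (kernel 3, stride 2, padding 1,
    output padding 1): output position o receives x[i] * W[k] wherever
    o = 2i + k - 1.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 slope: float = 0.01, dtype=np.float32, name: str = "up"):
        self.cin, self.cout = cin, cout
        fan_in = cin * _K ** 3 / 8.0  # stride-2: each output sees ~1/8 of taps
        w = rng.normal(0.0, _he_std(fan_in, slope),
                       size=(cin, cout, _K, _K, _K))
        self.w = Param(w.astype(dtype), f"{name}.w")
        self.b = Param(np.zeros(cout, dtype=dtype), f"{name}.b")
        self._cache = None

    def params(self):
        return [self.w, self.b]

    @staticmethod
    def _tap_slices(k: int, n: int):
        """(input slice, output slice) pairs along one axis for tap k."""
        if k == 0:
            return slice(1, n), slice(1, 2 * n - 2, 2)
        if k == 1:
            return slice(0, n), slice(0, 2 * n, 2)
        return slice(0, n), slice(1, 2 * n, 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        cin, d, h, w = x.shape
        out = np.zeros((self.cout, 2 * d, 2 * h, 2 * w), dtype=x.dtype)
        for kd, kh, kw in product(range(_K), repeat=3):
            sd, od = self._tap_slices(kd, d)
            sh, oh = self._tap_slices(kh, h)
            sw, ow = self._tap_slices(kw, w)
            sub = x[:, sd, sh, sw]
            contrib = np.tensordot(self.w.value[:, :, kd, kh, kw], sub,
                                   axes=([0], [0]))
            out[:, od, oh, ow] += contrib
        out += self.b.value[:, None, None, None]
        self._cache = x
        return out

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._cache
        cin, d, h, w = x.shape
        gx = np.zeros_like(x)
        for kd, kh, kw in product(range(_K), repeat=3):
            sd, od = self._tap_slices(kd, d)
            sh, oh = self._tap_slices(kh, h)
            sw, ow = self._tap_slices(kw, w)
            gsub = gy[:, od, oh, ow]
            xsub = x[:, sd, sh, sw]
            self.w.grad[:, :, kd, kh, kw] += np.tensordot(
                xsub, gsub, axes=([1, 2, 3], [1, 2, 3]))
            gx[:, sd, sh, sw] += np.tensordot(
                self.w.value[:, :, kd, kh, kw], gsub, axes=([1], [0]))
        self.b.grad += gy.sum(axis=(1, 2, 3))
        self._cache = None
        return gx


class InstanceNorm3d:
    """Per-channel standardization over the spatial axes, with affine."""

    def __init__(self, c: int, eps: float = 1e-5, dtype=np.float32,
                 name: str = "norm"):
        self.eps = eps
        self.gamma = Param(np.ones(c, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), f"{name}.beta")
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c = x.shape[0]
        flat = x.reshape(c, -1)
        mu = flat.mean(axis=1, keepdims=True)
        var = flat.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (flat - mu) * inv
        y = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        self._cache = (xhat, inv.astype(x.dtype))
        return y.reshape(x.shape).astype(x.dtype)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        c = gy.shape[0]
        g = gy.reshape(c, -1)
        self.gamma.grad += (g * xhat).sum(axis=1)
        self.beta.grad += g.sum(axis=1)
        gg = self.gamma.value[:, None] * g
        m1 = gg.mean(axis=1, keepdims=True)
        m2 = (gg * xhat).mean(axis=1, keepdims=True)
        gx = inv * (gg - m1 - xhat * m2)
        self._cache = None
        return gx.reshape(gy.shape).astype(gy.dtype)


class LeakyReLU:
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = np.where(self._mask, gy, self.slope * gy)
        self._mask = None
        return g


class MaxPool3d:
    """2x2x2 max pooling; requires even spatial sizes."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"spatial sizes must be even to pool, got {x.shape}")
        xr = x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)
        xr = xr.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, d // 2, h // 2, w // 2, 8)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        idx, shape = self._cache
        c, d, h, w = shape
        gxr = np.zeros((c, d // 2, h // 2, w // 2, 8), dtype=gy.dtype)
        np.put_along_axis(gxr, idx[..., None], gy[..., None], axis=-1)
        gx = gxr.reshape(c, d // 2, h // 2, w // 2, 2, 2, 2)
        gx = gx.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, d, h, w)
        self._cache = None
        return gx


class Adam:
    """Standard Adam over a flat parameter list; state is checkpointable."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.value, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad.astype(np.float64)
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            upd = (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps))
            p.value -= upd.astype(p.value.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def state_dict(self) -> dict:
        out = {"t": np.array(self.t), "lr": np.array(self.lr)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m
            out[f"v{i}"] = v
        return out

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        for i in range(len(self.params)):
            self.m[i] = np.asarray(state[f"m{i}"], dtype=np.float64)
            self.v[i] = np.asarray(state[f"v{i}"], dtype=np.float64)
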