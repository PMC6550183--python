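"""Minimal neural-network layers on numpy, NHWC layout.

Every layer supports ``forward`` and parameter counting; layers used by the
trainable small models additionally implement ``backward``.  The big ImageNet
backbones are assembled from these same primitives for inference and exact
parameter accounting.

Conventions
-----------
* activations are float32 arrays shaped ``(N, H, W, C)`` or ``(N, C)``
* ``padding`` is ``'same'`` (TensorFlow rule: total pad so that
  ``out = ceil(in / stride)``, extra pixel on bottom/right), ``'valid'``, or an
  integer for symmetric padding
* parameter counts include non-trainable batch-norm statistics, matching how
  deep-learning frameworks report model "total parameters"
"""

from __future__ import annotations

import math

import numpy as np

from ..errors import InvalidArgument


class Param:
    """A named tensor with an accumulated gradient."""

    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = None
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    """Base layer: forward required, backward optional (inference-only layers)."""

    def params(self) -> list[Param]:
        return []

    @property
    def param_count(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError(f"{type(self).__name__} has no backward pass")

    def inventory(self) -> list[str]:
        """Flattened list of primitive layer type names (for contract checks)."""
        return [type(self).__name__]


def _pad_amounts(size: int, k: int, stride: int, padding) -> tuple[int, int]:
    if padding == "valid":
        return 0, 0
    if padding == "same":
        out = math.ceil(size / stride)
        total = max((out - 1) * stride + k - size, 0)
        lo = total // 2
        return lo, total - lo
    p = int(padding)
    return p, p


class Conv2D(Layer):
    """2-D convolution. Weight shape (kh, kw, c_in, c_out)."""

    def __init__(self, c_in, c_out, k, stride=1, padding="same", use_bias=True,
                 name="conv", rng=None):
        self.kh, self.kw = (k, k) if np.isscalar(k) else k
        self.c_in, self.c_out = c_in, c_out
        self.stride = stride
        self.padding = padding
        self.use_bias = use_bias
        rng = rng or np.random.default_rng(0)
        fan_in = self.kh * self.kw * c_in
        w = rng.normal(0.0, math.sqrt(2.0 / fan_in),
                       size=(self.kh, self.kw, c_in, c_out))
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(c_out)) if use_bias else None
        self._cache = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def _pad(self, x):
        pt, pb = _pad_amounts(x.shape[1], self.kh, self.stride, self.padding)
        pl, pr = _pad_amounts(x.shape[2], self.kw, self.stride, self.padding)
        if pt or pb or pl or pr:
            x = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        return x, (pt, pb, pl, pr)

    def forward(self, x, training=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        xp, pads = self._pad(x)
        s = self.stride
        ho = (xp.shape[1] - self.kh) // s + 1
        wo = (xp.shape[2] - self.kw) // s + 1
        out = np.zeros((x.shape[0], ho, wo, self.c_out), dtype=np.float32)
        out_flat = out.reshape(-1, self.c_out)
        # sum of kh*kw small matmuls keeps memory flat (no full im2col buffer)
        for i in range(self.kh):
            for j in range(self.kw):
                sl = xp[:, i:i + ho * s:s, j:j + wo * s:s, :]
                out_flat += np.ascontiguousarray(sl).reshape(-1, self.c_in) \
                    @ self.w.value[i, j]
        if self.b is not None:
            out += self.b.value
        if training:
            self._cache = (xp, pads, x.shape, ho, wo)
        return out

    def backward(self, grad):
        xp, pads, xshape, ho, wo = self._cache
        s = self.stride
        g2 = grad.reshape(-1, self.c_out)
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(self.w.value)
        for i in range(self.kh):
            for j in range(self.kw):
                sl = np.ascontiguousarray(xp[:, i:i + ho * s:s, j:j + wo * s:s, :])
                dw[i, j] = sl.reshape(-1, self.c_in).T @ g2
                dxp[:, i:i + ho * s:s, j:j + wo * s:s, :] += (
                    g2 @ self.w.value[i, j].T).reshape(sl.shape)
        self.w.grad = dw if self.w.grad is None else self.w.grad + dw
        if self.b is not None:
            db = g2.sum(axis=0)
            self.b.grad = db if self.b.grad is None else self.b.grad + db
        pt, pb, pl, pr = pads
        h, w = xshape[1], xshape[2]
        return dxp[:, pt:pt + h, pl:pl + w, :]


class DepthwiseConv2D(Layer):
    """Per-channel convolution (MobileNet). Weight shape (kh, kw, c). Inference only."""

    def __init__(self, c, k=3, stride=1, padding="same", use_bias=False, name="dwconv",
                 rng=None):
        self.kh, self.kw = (k, k) if np.isscalar(k) else k
        self.c = c
        self.stride = stride
        self.padding = padding
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, math.sqrt(2.0 / (self.kh * self.kw)),
                       size=(self.kh, self.kw, c))
        self.w = Param(f"{name}.w", w)
        self.b = Param(f"{name}.b", np.zeros(c)) if use_bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False):
        pt, pb = _pad_amounts(x.shape[1], self.kh, self.stride, self.padding)
        pl, pr = _pad_amounts(x.shape[2], self.kw, self.stride, self.padding)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0))).astype(np.float32)
        s = self.stride
        ho = (xp.shape[1] - self.kh) // s + 1
        wo = (xp.shape[2] - self.kw) // s + 1
        out = np.zeros((x.shape[0], ho, wo, self.c), dtype=np.float32)
        for i in range(self.kh):
            for j in range(self.kw):
                out += xp[:, i:i + ho * s:s, j:j + wo * s:s, :] * self.w.value[i, j]
        if self.b is not None:
            out += self.b.value
        return out


class Dense(Layer):
    def __init__(self, n_in, n_out, use_bias=True, name="dense", rng=None):
        rng = rng or np.random.default_rng(0)
        limit = math.sqrt(6.0 / (n_in + n_out))
        self.w = Param(f"{name}.w", rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Param(f"{name}.b", np.zeros(n_out)) if use_bias else None
        self._x = None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        if training:
            self._x = x
        out = x @ self.w.value
        if self.b is not None:
            out += self.b.value
        return out

    def backward(self, grad):
        dw = self._x.T @ grad
        self.w.grad = dw if self.w.grad is None else self.w.grad + dw
        if self.b is not None:
            db = grad.sum(axis=0)
            self.b.grad = db if self.b.grad is None else self.b.grad + db
        return grad @ self.w.value.T


class BatchNorm(Layer):
    """Batch normalization over the channel axis.

    ``scale=False`` omits gamma (used by Inception-style backbones).  Parameter
    count includes the moving mean/variance, as frameworks report them.
    """

    def __init__(self, c, scale=True, eps=1e-3, momentum=0.99, name="bn"):
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(c)) if scale else None
        self.beta = Param(f"{name}.beta", np.zeros(c))
        self.moving_mean = Param(f"{name}.moving_mean", np.zeros(c), trainable=False)
        self.moving_var = Param(f"{name}.moving_var", np.ones(c), trainable=False)
        self._cache = None

    def params(self):
        ps = [self.beta, self.moving_mean, self.moving_var]
        if self.gamma is not None:
            ps = [self.gamma] + ps
        return ps

    def forward(self, x, training=False):
        x = np.asarray(x, dtype=np.float32)
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean.value = m * self.moving_mean.value + (1 - m) * mean
            self.moving_var.value = m * self.moving_var.value + (1 - m) * var
        else:
            mean, var = self.moving_mean.value, self.moving_var.value
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._cache = (xhat, inv, axes, x.shape)
        out = xhat
        if self.gamma is not None:
            out = out * self.gamma.value
        return out + self.beta.value

    def backward(self, grad):
        xhat, inv, axes, shape = self._cache
        n = int(np.prod([shape[a] for a in axes]))
        g = self.gamma.value if self.gamma is not None else 1.0
        dbeta = grad.sum(axis=axes)
        self.beta.grad = dbeta if self.beta.grad is None else self.beta.grad + dbeta
        dgamma = (grad * xhat).sum(axis=axes)
        if self.gamma is not None:
            self.gamma.grad = (dgamma if self.gamma.grad is None
                               else self.gamma.grad + dgamma)
        dxhat = grad * g
        return inv * (dxhat - dxhat.mean(axis=axes)
                      - xhat * (dxhat * xhat).sum(axis=axes) / n)


class Dropout(Layer):
    def __init__(self, rate, seed=0):
        if not 0.0 <= rate < 1.0:
            raise InvalidArgument(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = np.random.default_rng(seed)
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, training=False):
        if training:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def __init__(self):
        self._out = None

    def forward(self, x, training=False):
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if training:
            self._out = out
        return out

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class MaxPool2D(Layer):
    def __init__(self, pool=2, stride=None, padding="valid"):
        self.ph, self.pw = (pool, pool) if np.isscalar(pool) else pool
        self.stride = stride or self.ph
        self.padding = padding
        self._cache = None

    def forward(self, x, training=False):
        s = self.stride
        if (self.padding == "valid" and s == self.ph == self.pw
                and x.shape[1] % s == 0 and x.shape[2] % s == 0):
            n, h, w, c = x.shape
            xr = x.reshape(n, h // s, s, w // s, s, c)
            out = xr.max(axis=(2, 4))
            if training:
                self._cache = (xr, out, x.shape)
            return out
        # general (possibly padded / overlapping) pooling: inference only
        pt, pb = _pad_amounts(x.shape[1], self.ph, s, self.padding)
        pl, pr = _pad_amounts(x.shape[2], self.pw, s, self.padding)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)),
                    constant_values=-np.inf)
        ho = (xp.shape[1] - self.ph) // s + 1
        wo = (xp.shape[2] - self.pw) // s + 1
        out = np.full((x.shape[0], ho, wo, x.shape[3]), -np.inf, dtype=np.float32)
        for i in range(self.ph):
            for j in range(self.pw):
                np.maximum(out, xp[:, i:i + ho * s:s, j:j + wo * s:s, :], out=out)
        return out

    def backward(self, grad):
        xr, out, shape = self._cache
        n, h, w, c = shape
        s = self.stride
        mask = xr == out[:, :, None, :, None, :]
        # spread gradient to argmax positions (ties split evenly)
        counts = mask.sum(axis=(2, 4), keepdims=True)
        g = mask * (grad[:, :, None, :, None, :] / counts)
        return g.reshape(shape)


class AvgPool2D(Layer):
    """Average pooling (inference only; used inside Inception branches)."""

    def __init__(self, pool=3, stride=1, padding="same"):
        self.ph, self.pw = (pool, pool) if np.isscalar(pool) else pool
        self.stride = stride
        self.padding = padding

    def forward(self, x, training=False):
        s = self.stride
        pt, pb = _pad_amounts(x.shape[1], self.ph, s, self.padding)
        pl, pr = _pad_amounts(x.shape[2], self.pw, s, self.padding)
        xp = np.pad(x, ((0, 0), (pt, pb), (pl, pr), (0, 0)))
        cnt = np.pad(np.ones(x.shape[1:3], dtype=np.float32),
                     ((pt, pb), (pl, pr)))
        ho = (xp.shape[1] - self.ph) // s + 1
        wo = (xp.shape[2] - self.pw) // s + 1
        out = np.zeros((x.shape[0], ho, wo, x.shape[3]), dtype=np.float32)
        den = np.zeros((ho, wo), dtype=np.float32)
        for i in range(self.ph):
            for j in range(self.pw):
                out += xp[:, i:i + ho * s:s, j:j + wo * s:s, :]
                den += cnt[i:i + ho * s:s, j:j + wo * s:s]
        return out / den[None, :, :, None]


class GlobalAvgPool(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, grad):
        n, h, w, c = self._shape
        return np.broadcast_to(grad[:, None, None, :] / (h * w),
                               self._shape).astype(np.float32)


class UpSample2D(Layer):
    """Nearest-neighbour spatial upsampling."""

    def __init__(self, factor=2):
        self.factor = factor

    def forward(self, x, training=False):
        f = self.factor
        return x.repeat(f, axis=1).repeat(f, axis=2)

    def backward(self, grad):
        f = self.factor
        n, h, w, c = grad.shape
        return grad.reshape(n, h // f, f, w // f, f, c).sum(axis=(2, 4))
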