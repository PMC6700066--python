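"""Minimal CPU neural-network layers with explicit backpropagation.

The training environment provides no deep-learning framework, so the few
primitives the super-resolver needs — same-padded 3x3 convolution, leaky
ReLU, 2x average pooling, nearest/zero-stuffed 2x upsampling, dense heads and
Adam — are implemented directly on numpy.  Convolution is evaluated as an
im2col matrix product; its input gradient is the correlation of the output
gradient with the channel-transposed, 180-degree-rotated kernels, which
reuses the same im2col machinery.

Tensors are ``(batch, channels, height, width)`` float64 throughout; float64
keeps the analytic/numeric gradient checks tight.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) already padded -> (B*Ho*Wo, C*k*k) patch matrix."""
    b, c, h, w = x.shape
    ho, wo = h - k + 1, w - k + 1
    s = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x, (b, ho, wo, c, k, k), (s[0], s[2], s[3], s[1], s[2], s[3])
    )
    return cols.reshape(b * ho * wo, c * k * k)


class Conv2d:
    """Same-padded (zero) convolution with odd kernel size."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None,
                 weight_scale: float | None = None):
        assert k % 2 == 1, "kernel size must be odd"
        rng = rng or np.random.default_rng(0)
        scale = weight_scale if weight_scale is not None else np.sqrt(2.0 / (c_in * k * k))
        self.w = Param(rng.standard_normal((c_out, c_in, k, k)) * scale)
        self.b = Param(np.zeros(c_out))
        self.k = k
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = _im2col(xp, self.k)
        self._cols = cols
        self._xshape = x.shape
        c_out = self.w.value.shape[0]
        out = cols @ self.w.value.reshape(c_out, -1).T + self.b.value
        b, _, h, w = x.shape
        return out.reshape(b, h, w, c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._cols is not None and self._xshape is not None
        b, c_in, h, w = self._xshape
        c_out = self.w.value.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, c_out)
        self.w.grad += (dflat.T @ self._cols).reshape(self.w.value.shape)
        self.b.grad += dflat.sum(axis=0)
        # input gradient: correlate dout with channel-swapped rotated kernels
        p = self.k // 2
        dp = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        cols_d = _im2col(dp, self.k)
        w_rot = self.w.value.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1].reshape(c_in, -1)
        dx = (cols_d @ w_rot.T).reshape(b, h, w, c_in).transpose(0, 3, 1, 2)
        self._cols = None
        return dx


class LeakyReLU:
    params: list[Param] = []

    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        assert self._mask is not None
        return np.where(self._mask, dout, self.slope * dout)


class AvgPool2:
    """2x2 average pooling (dimensions must be even)."""

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


class UpNearest2:
    """Nearest-neighbour 2x upsampling."""

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class UpZeroStuff2:
    """Zero-stuffing 2x upsampling; followed by a conv it realises a
    transposed (fractionally-strided) convolution."""

    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        out = np.zeros((b, c, 2 * h, 2 * w), dtype=x.dtype)
        out[:, :, ::2, ::2] = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout[:, :, ::2, ::2]


class GlobalAvgPool:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Dense:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(rng.standard_normal((c_out, c_in)) * np.sqrt(2.0 / c_in))
        self.b = Param(np.zeros(c_out))

    @property
    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value.T + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += dout.T @ self._x
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value


class Sigmoid:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._y * (1.0 - self._y)


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    @property
    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def parameter_count(params: list[Param]) -> int:
    return int(sum(p.value.size for p in params))


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of a scalar function, for test oracles."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        orig = x[idx]
        x[idx] = orig + eps
        fp = f(x)
        x[idx] = orig - eps
        fm = f(x)
        x[idx] = orig
        g[idx] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
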