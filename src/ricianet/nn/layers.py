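"""Minimal NumPy layer stack used by the parallel denoising network.

Every layer implements ``forward(x, training)`` and ``backward(grad)`` and
exposes its weights through :meth:`Layer.param_entries`, so the whole network
can be trained with explicit reverse-mode differentiation and inspected by the
parameter counter.  Convolutions are evaluated as a sum over kernel offsets,
each offset contributing a channel-mixing matmul on a shifted view of the
zero-padded input; this keeps the inner loop in BLAS and supports arbitrary
dilation rates in 2-D and 3-D with symmetric "same" padding.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv",
    "DepthwiseConv",
    "BatchNorm",
    "LeakyReLU",
]


class Param:
    """A named weight array with its gradient accumulator."""

    __slots__ = ("name", "value", "grad", "trainable")

    def __init__(self, name: str, value: np.ndarray, trainable: bool = True):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.trainable = trainable


class Layer:
    def param_entries(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
             slope: float) -> np.ndarray:
    # variance-scaling (fan-in) normal init with leaky-rectifier gain
    gain = np.sqrt(2.0 / (1.0 + slope * slope))
    std = gain / np.sqrt(fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv(Layer):
    """Dilated N-D convolution (cross-correlation) with symmetric zero padding.

    Weight shape is ``(out_channels, in_channels, k, ..., k)`` with ``dim``
    trailing kernel axes.  ``rate`` is the dilation rate; the effective
    per-axis extent is ``(k - 1) * rate + 1`` and the padding is chosen so the
    spatial shape is preserved (``k`` must be odd).
    """

    def __init__(self, dim: int, in_channels: int, out_channels: int,
                 kernel: int = 3, rate: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None, slope: float = 0.3,
                 name: str = "conv"):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for symmetric padding")
        if rate < 1:
            raise ValueError("dilation rate must be >= 1")
        self.dim = dim
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.rate = rate
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_channels * kernel**dim
        wshape = (out_channels, in_channels) + (kernel,) * dim
        self.W = Param(f"{name}.weight", _he_init(rng, wshape, fan_in, slope))
        self.b = Param(f"{name}.bias", np.zeros(out_channels, np.float32)) if bias else None
        self._xp: np.ndarray | None = None

    def param_entries(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def _offsets(self):
        return itertools.product(range(self.kernel), repeat=self.dim)

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        pad = (self.kernel - 1) * self.rate // 2
        xp = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * self.dim)
        self._xp = xp
        n = x.shape[0]
        spatial = x.shape[2:]
        size = int(np.prod(spatial))
        wf = self.W.value.reshape(self.out_channels, self.in_channels, -1)
        out = np.zeros((n, self.out_channels, size),
                       dtype=np.result_type(x.dtype, np.float32))
        for o, idx in enumerate(self._offsets()):
            sl = tuple(slice(i * self.rate, i * self.rate + spatial[a])
                       for a, i in enumerate(idx))
            xs = xp[(slice(None), slice(None)) + sl].reshape(n, self.in_channels, size)
            out += np.matmul(wf[:, :, o], xs)
        if self.b is not None:
            out += self.b.value[None, :, None]
        return out.reshape((n, self.out_channels) + spatial)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        if xp is None:
            raise RuntimeError("backward called before a training-mode forward")
        n = grad.shape[0]
        spatial = grad.shape[2:]
        size = int(np.prod(spatial))
        g2 = np.ascontiguousarray(grad.reshape(n, self.out_channels, size))
        wf = self.W.value.reshape(self.out_channels, self.in_channels, -1)
        gw = np.zeros_like(wf)
        gxp = np.zeros_like(xp)
        for o, idx in enumerate(self._offsets()):
            sl = tuple(slice(i * self.rate, i * self.rate + spatial[a])
                       for a, i in enumerate(idx))
            view = xp[(slice(None), slice(None)) + sl]
            xs = view.reshape(n, self.in_channels, size)
            gw[:, :, o] = np.einsum("nos,nis->oi", g2, xs, optimize=True)
            gxp[(slice(None), slice(None)) + sl] += np.matmul(
                wf[:, :, o].T, g2).reshape((n, self.in_channels) + spatial)
        self.W.grad += gw.reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += g2.sum(axis=(0, 2))
        pad = (self.kernel - 1) * self.rate // 2
        if pad == 0:
            return gxp
        crop = (slice(None), slice(None)) + (slice(pad, -pad),) * self.dim
        return gxp[crop]


class DepthwiseConv(Layer):
    """Per-channel spatial convolution (the depthwise half of a DSConv)."""

    def __init__(self, dim: int, channels: int, kernel: int = 3,
                 bias: bool = True, rng: np.random.Generator | None = None,
                 slope: float = 0.3, name: str = "dwconv"):
        if kernel % 2 == 0:
            raise ValueError("kernel size must be odd for symmetric padding")
        self.dim = dim
        self.channels = channels
        self.kernel = kernel
        rng = rng if rng is not None else np.random.default_rng(0)
        wshape = (channels,) + (kernel,) * dim
        self.W = Param(f"{name}.weight", _he_init(rng, wshape, kernel**dim, slope))
        self.b = Param(f"{name}.bias", np.zeros(channels, np.float32)) if bias else None
        self._xp: np.ndarray | None = None

    def param_entries(self) -> list[Param]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        pad = (self.kernel - 1) // 2
        xp = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * self.dim)
        self._xp = xp
        spatial = x.shape[2:]
        wf = self.W.value.reshape(self.channels, -1)
        out = np.zeros_like(x)
        shape_w = (1, self.channels) + (1,) * self.dim
        for o, idx in enumerate(itertools.product(range(self.kernel), repeat=self.dim)):
            sl = tuple(slice(i, i + spatial[a]) for a, i in enumerate(idx))
            out += wf[:, o].reshape(shape_w) * xp[(slice(None), slice(None)) + sl]
        if self.b is not None:
            out += self.b.value.reshape(shape_w)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xp = self._xp
        if xp is None:
            raise RuntimeError("backward called before a training-mode forward")
        spatial = grad.shape[2:]
        wf = self.W.value.reshape(self.channels, -1)
        gw = np.zeros_like(wf)
        gxp = np.zeros_like(xp)
        axes = (0,) + tuple(range(2, 2 + self.dim))
        shape_w = (1, self.channels) + (1,) * self.dim
        for o, idx in enumerate(itertools.product(range(self.kernel), repeat=self.dim)):
            sl = tuple(slice(i, i + spatial[a]) for a, i in enumerate(idx))
            view = xp[(slice(None), slice(None)) + sl]
            gw[:, o] = (grad * view).sum(axis=axes)
            gxp[(slice(None), slice(None)) + sl] += wf[:, o].reshape(shape_w) * grad
        self.W.grad += gw.reshape(self.W.value.shape)
        if self.b is not None:
            self.b.grad += grad.sum(axis=axes)
        pad = (self.kernel - 1) // 2
        if pad == 0:
            return gxp
        crop = (slice(None), slice(None)) + (slice(pad, -pad),) * self.dim
        return gxp[crop]


class BatchNorm(Layer):
    """Per-channel batch normalization with affine terms and running stats."""

    def __init__(self, channels: int, dim: int, eps: float = 1e-3,
                 momentum: float = 0.9, name: str = "bn"):
        self.channels = channels
        self.dim = dim
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(f"{name}.gamma", np.ones(channels, np.float32))
        self.beta = Param(f"{name}.beta", np.zeros(channels, np.float32))
        self.running_mean = Param(f"{name}.running_mean",
                                  np.zeros(channels, np.float32), trainable=False)
        self.running_var = Param(f"{name}.running_var",
                                 np.ones(channels, np.float32), trainable=False)
        self._cache = None

    def param_entries(self) -> list[Param]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def _cshape(self):
        return (1, self.channels) + (1,) * self.dim

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        axes = (0,) + tuple(range(2, 2 + self.dim))
        cs = self._cshape()
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean.reshape(cs)) * inv.reshape(cs)
            m = self.momentum
            self.running_mean.value = (m * self.running_mean.value
                                       + (1 - m) * mean).astype(np.float32)
            self.running_var.value = (m * self.running_var.value
                                      + (1 - m) * var).astype(np.float32)
            self._cache = (xhat, inv, True)
        else:
            inv = 1.0 / np.sqrt(self.running_var.value + self.eps)
            xhat = (x - self.running_mean.value.reshape(cs)) * inv.reshape(cs)
            self._cache = (xhat, inv, False)
        return self.gamma.value.reshape(cs) * xhat + self.beta.value.reshape(cs)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, was_training = self._cache
        axes = (0,) + tuple(range(2, 2 + self.dim))
        cs = self._cshape()
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        gterm = grad * self.gamma.value.reshape(cs)
        if not was_training:
            # eval-mode statistics are constants
            return gterm * inv.reshape(cs)
        count = grad.size // self.channels
        mean_g = gterm.sum(axis=axes) / count
        mean_gx = (gterm * xhat).sum(axis=axes) / count
        return inv.reshape(cs) * (gterm - mean_g.reshape(cs)
                                  - xhat * mean_gx.reshape(cs))



class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.3):
        self.slope = slope
        self._mask = None

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        mask = x >= 0
        self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, self.slope * grad)
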