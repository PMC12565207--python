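"""Minimal 3-D convolutional layer framework with explicit backward passes.

Layers operate on arrays of shape ``(N, C, D, H, W)``.  Each layer implements
``forward(x, mode)`` (caching whatever backward needs) and ``backward(gy)``
(returning the input gradient and accumulating parameter gradients into
``Param.grad``).  ``Mode`` carries the training flag, the dropout RNG and the
MC-dropout switch.  All backward passes are verified against central finite
differences in the test suite.

Convolutions are realized as a sum over kernel offsets of strided slices,
with the channel mixing done by BLAS ``tensordot`` — no im2col buffer, which
keeps memory flat for volumetric inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np


@dataclass
class Mode:
    """Forward-pass context: training flag, RNG for dropout, MC-dropout switch."""

    training: bool = False
    rng: Optional[np.random.Generator] = None
    mc_dropout: bool = False

    @property
    def stochastic(self) -> bool:
        return self.training or self.mc_dropout


EVAL = Mode(training=False)


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = ""):
        self.data = data
        self.grad = np.zeros_like(data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size


class Layer:
    def forward(self, x: np.ndarray, mode: Mode = EVAL) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> Iterable[Param]:
        return ()

    def children(self) -> Iterable["Layer"]:
        return ()

    def __call__(self, x: np.ndarray, mode: Mode = EVAL) -> np.ndarray:
        return self.forward(x, mode)


def walk_layers(layer: "Layer"):
    """Depth-first traversal of a layer tree (the layer itself included)."""
    yield layer
    for child in layer.children():
        yield from walk_layers(child)


def he_init(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv3d(Layer):
    """3-D convolution, kernel 1 or 3, stride 1 or 2, groups 1 (dense) or C (depthwise).

    Padding is ``k // 2`` (shape-preserving at stride 1).  Convolutions feeding
    a batch norm carry no bias; ``bias=True`` only on the network head.
    """

    def __init__(self, cin, cout, k=3, stride=1, groups=1, bias=False,
                 rng=None, dtype=np.float32):
        if groups not in (1, cin) or (groups == cin and cout != cin and groups != 1):
            raise ValueError("groups must be 1 (dense) or cin==cout (depthwise)")
        if stride not in (1, 2):
            raise ValueError(f"unsupported stride {stride}")
        self.cin, self.cout, self.k, self.stride, self.groups = cin, cout, k, stride, groups
        self.pad = k // 2
        rng = rng or np.random.default_rng(0)
        fan_in = (cin // groups) * k**3
        self.w = Param(he_init(rng, (cout, cin // groups, k, k, k), fan_in, dtype), "w")
        self.b = Param(np.zeros(cout, dtype=dtype), "b") if bias else None
        self._xp: np.ndarray | None = None

    def params(self):
        yield self.w
        if self.b is not None:
            yield self.b

    def _out_shape(self, spatial):
        return tuple((s + 2 * self.pad - self.k) // self.stride + 1 for s in spatial)

    def forward(self, x, mode=EVAL):
        n, cin = x.shape[:2]
        assert cin == self.cin, f"expected {self.cin} channels, got {cin}"
        p, k, s = self.pad, self.k, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        do, ho, wo = self._out_shape(x.shape[2:])
        self._xp = xp
        self._xshape = x.shape
        out = np.zeros((n, self.cout, do, ho, wo), dtype=x.dtype)
        w = self.w.data
        for a in range(k):
            for b_ in range(k):
                for c in range(k):
                    xs = xp[:, :, a:a + s * do:s, b_:b_ + s * ho:s, c:c + s * wo:s]
                    if self.groups == 1:
                        # (cout, cin) x (n, cin, d, h, w) -> (n, cout, d, h, w)
                        out += np.moveaxis(
                            np.tensordot(w[:, :, a, b_, c], xs, axes=([1], [1])), 1, 0
                        )
                    else:
                        out += w[:, 0, a, b_, c][None, :, None, None, None] * xs
        if self.b is not None:
            out += self.b.data[None, :, None, None, None]
        return out

    def backward(self, gy):
        xp = self._xp
        p, k, s = self.pad, self.k, self.stride
        n, _, do, ho, wo = gy.shape
        gxp = np.zeros_like(xp)
        w = self.w.data
        for a in range(k):
            for b_ in range(k):
                for c in range(k):
                    sl = (slice(None), slice(None),
                          slice(a, a + s * do, s),
                          slice(b_, b_ + s * ho, s),
                          slice(c, c + s * wo, s))
                    xs = xp[sl]
                    if self.groups == 1:
                        self.w.grad[:, :, a, b_, c] += np.tensordot(
                            gy, xs, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
                        gxp[sl] += np.moveaxis(
                            np.tensordot(w[:, :, a, b_, c].T, gy, axes=([1], [1])), 1, 0)
                    else:
                        self.w.grad[:, 0, a, b_, c] += np.einsum(
                            "ncdhw,ncdhw->c", gy, xs, optimize=True)
                        gxp[sl] += w[:, 0, a, b_, c][None, :, None, None, None] * gy
        if self.b is not None:
            self.b.grad += gy.sum(axis=(0, 2, 3, 4))
        if p:
            d, h, wd = self._xshape[2:]
            return gxp[:, :, p:p + d, p:p + h, p:p + wd]
        return gxp


class ConvTranspose3d(Layer):
    """Transposed convolution with kernel 2, stride 2 (exact 2x upsampling)."""

    def __init__(self, cin, cout, rng=None, dtype=np.float32):
        self.cin, self.cout = cin, cout
        rng = rng or np.random.default_rng(0)
        self.w = Param(he_init(rng, (cin, cout, 2, 2, 2), cin, dtype), "w")
        self._x = None

    def params(self):
        yield self.w

    def forward(self, x, mode=EVAL):
        n, cin, d, h, wd = x.shape
        self._x = x
        out = np.empty((n, self.cout, 2 * d, 2 * h, 2 * wd), dtype=x.dtype)
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    # (n, cin, d, h, w) x (cin, cout) -> (n, cout, d, h, w)
                    out[:, :, a::2, b::2, c::2] = np.moveaxis(
                        np.tensordot(self.w.data[:, :, a, b, c], x, axes=([0], [1])), 1, 0)
        return out

    def backward(self, gy):
        x = self._x
        gx = np.zeros_like(x)
        for a in range(2):
            for b in range(2):
                for c in range(2):
                    gys = gy[:, :, a::2, b::2, c::2]
                    self.w.grad[:, :, a, b, c] += np.tensordot(
                        x, gys, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
                    gx += np.moveaxis(
                        np.tensordot(self.w.data[:, :, a, b, c], gys, axes=([1], [1])), 1, 0)
        return gx


class BatchNorm3d(Layer):
    """Per-channel batch normalization over ``(N, D, H, W)`` with running stats."""

    def __init__(self, c, momentum=0.1, eps=1e-5, dtype=np.float32):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(np.ones(c, dtype=dtype), "gamma")
        self.beta = Param(np.zeros(c, dtype=dtype), "beta")
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self._cache = None

    def params(self):
        yield self.gamma
        yield self.beta

    def forward(self, x, mode=EVAL):
        axes = (0, 2, 3, 4)
        if mode.training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)  # population variance
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        std = np.sqrt(var + self.eps).astype(x.dtype)
        xhat = (x - mean[None, :, None, None, None]) / std[None, :, None, None, None]
        self._cache = (xhat, std, mode.training)
        return self.gamma.data[None, :, None, None, None] * xhat \
            + self.beta.data[None, :, None, None, None]

    def backward(self, gy):
        xhat, std, was_training = self._cache
        axes = (0, 2, 3, 4)
        self.gamma.grad += (gy * xhat).sum(axis=axes)
        self.beta.grad += gy.sum(axis=axes)
        g = self.gamma.data[None, :, None, None, None]
        if not was_training:
            return gy * g / std[None, :, None, None, None]
        gxhat = gy * g
        m = gxhat.mean(axis=axes, keepdims=True)
        mx = (gxhat * xhat).mean(axis=axes, keepdims=True)
        return (gxhat - m - xhat * mx) / std[None, :, None, None, None]


class Swish(Layer):
    """x * sigmoid(x) (a.k.a. SiLU)."""

    def forward(self, x, mode=EVAL):
        e = np.exp(-np.abs(x))  # overflow-safe sigmoid
        s = np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
        self._cache = (x, s)
        return x * s

    def backward(self, gy):
        x, s = self._cache
        return gy * (s + x * s * (1.0 - s))


class ReLU(Layer):
    def forward(self, x, mode=EVAL):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Sigmoid(Layer):
    def forward(self, x, mode=EVAL):
        out = np.empty_like(x)
        np.negative(np.abs(x), out=out)
        np.exp(out, out=out)
        out = np.where(x >= 0, 1.0 / (1.0 + out), out / (1.0 + out))
        self._y = out
        return out

    def backward(self, gy):
        y = self._y
        return gy * y * (1.0 - y)


class MaxPool3d(Layer):
    """2x2x2 max pooling; spatial dims must be even."""

    def forward(self, x, mode=EVAL):
        n, c, d, h, w = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"MaxPool3d needs even spatial dims, got {(d, h, w)}")
        xr = x.reshape(n, c, d // 2, 2, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5, 7))
        mask = xr == out[:, :, :, None, :, None, :, None]
        count = mask.sum(axis=(3, 5, 7), keepdims=True)
        self._cache = (mask, count, x.shape)
        return out

    def backward(self, gy):
        mask, count, xshape = self._cache
        n, c, d, h, w = xshape
        gyr = gy[:, :, :, None, :, None, :, None]
        gx = mask * (gyr / count)
        return gx.reshape(n, c, d, h, w)


def _up2_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Linear 2x upsampling (half-voxel aligned) along one axis."""
    x = np.moveaxis(x, axis, -1)
    left = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    right = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=x.dtype)
    out[..., 0::2] = 0.75 * x + 0.25 * left
    out[..., 1::2] = 0.75 * x + 0.25 * right
    return np.moveaxis(out, -1, axis)


def _up2_axis_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    ge, go = g[..., 0::2], g[..., 1::2]
    gx = 0.75 * (ge + go)
    gx[..., :-1] += 0.25 * ge[..., 1:]
    gx[..., 0] += 0.25 * ge[..., 0]
    gx[..., 1:] += 0.25 * go[..., :-1]
    gx[..., -1] += 0.25 * go[..., -1]
    return np.moveaxis(gx, -1, axis)


class TrilinearUpsample2x(Layer):
    """Separable trilinear 2x upsampling (exact adjoint in backward)."""

    def forward(self, x, mode=EVAL):
        for axis in (2, 3, 4):
            x = _up2_axis(x, axis)
        return x

    def backward(self, gy):
        for axis in (4, 3, 2):
            gy = _up2_axis_adjoint(gy, axis)
        return gy


class SpatialDropout3d(Layer):
    """Channel-wise dropout; active in training or when MC-dropout is requested."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self._mask = None

    def forward(self, x, mode=EVAL):
        if self.p == 0.0 or not mode.stochastic:
            self._mask = None
            return x
        rng = mode.rng if mode.rng is not None else np.random.default_rng(0)
        keep = (rng.random((x.shape[0], x.shape[1], 1, 1, 1)) >= self.p)
        self._mask = keep.astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        return gy * self._mask


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, mode=EVAL):
        for layer in self.layers:
            x = layer.forward(x, mode)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def params(self):
        for layer in self.layers:
            yield from layer.params()

    def children(self):
        return self.layers


class MBConv3d(Layer):
    """Inverted-bottleneck 3-D block: expand (1x1x1) -> depthwise 3x3x3 -> project.

    Batch norm follows every convolution; Swish after expansion and depthwise,
    linear after projection.  A residual shortcut applies iff stride is 1 and
    the channel count is preserved.  The expansion stage is omitted entirely
    when the expansion factor is 1.
    """

    def __init__(self, cin, cout, stride=1, expansion=1, rng=None, dtype=np.float32):
        if expansion < 1:
            raise ValueError("expansion factor must be >= 1")
        mid = cin * expansion
        self.use_residual = stride == 1 and cin == cout
        layers: list[Layer] = []
        if expansion > 1:
            layers += [Conv3d(cin, mid, k=1, rng=rng, dtype=dtype),
                       BatchNorm3d(mid, dtype=dtype), Swish()]
        layers += [
            Conv3d(mid, mid, k=3, stride=stride, groups=mid, rng=rng, dtype=dtype),
            BatchNorm3d(mid, dtype=dtype), Swish(),
            Conv3d(mid, cout, k=1, rng=rng, dtype=dtype),
            BatchNorm3d(cout, dtype=dtype),
        ]
        self.body = Sequential(*layers)

    def forward(self, x, mode=EVAL):
        out = self.body.forward(x, mode)
        if self.use_residual:
            out = out + x
        return out

    def backward(self, gy):
        gx = self.body.backward(gy)
        if self.use_residual:
            gx = gx + gy
        return gx

    def params(self):
        yield from self.body.params()

    def children(self):
        return (self.body,)


class DoubleConv3d(Layer):
    """Two (conv 3x3x3 -> BN -> ReLU) stages; the classic U-Net unit."""

    def __init__(self, cin, cout, rng=None, dtype=np.float32):
        self.body = Sequential(
            Conv3d(cin, cout, k=3, rng=rng, dtype=dtype),
            BatchNorm3d(cout, dtype=dtype), ReLU(),
            Conv3d(cout, cout, k=3, rng=rng, dtype=dtype),
            BatchNorm3d(cout, dtype=dtype), ReLU(),
        )

    def forward(self, x, mode=EVAL):
        return self.body.forward(x, mode)

    def backward(self, gy):
        return self.body.backward(gy)

    def params(self):
        yield from self.body.params()

    def children(self):
        return (self.body,)
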