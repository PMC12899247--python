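"""Minimal NumPy neural-network engine used by the model kit.

Implements exactly the primitives the detector needs — grouped/dilated 2-D
convolution, batch normalization, SiLU/ReLU/sigmoid, stride-1 max pooling,
nearest-neighbour upsampling, channel statistics — with reverse-mode
automatic differentiation so small models can be trained on CPU, plus a
shape-probe mode that walks the same forward code to count convolution
FLOPs analytically (1 multiply-accumulate = 2 FLOPs) without touching any
pixel data.

All arrays are float32, layout (batch, channels, height, width).
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "ShapeProbe",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "SiLU",
    "ReLU",
    "Sigmoid",
    "Identity",
    "MaxPool2d",
    "Upsample",
    "cat",
    "add",
    "mul",
    "narrow",
    "channel_mean",
    "channel_max",
    "scalar_bias",
    "backward",
    "SGD",
]


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


class ShapeProbe:
    """Stand-in for a Tensor that carries only a shape and a FLOP counter.

    Passing a probe through ``Module.forward`` exercises the identical
    wiring as a real forward pass, so the analytic FLOP count can never
    drift from the implementation.
    """

    __slots__ = ("shape", "counter")

    def __init__(self, shape: Sequence[int], counter: dict | None = None):
        self.shape = tuple(int(s) for s in shape)
        self.counter = counter if counter is not None else {"flops": 0}

    def like(self, shape) -> "ShapeProbe":
        return ShapeProbe(shape, self.counter)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def backward(outputs: Sequence[Tensor], grads: Sequence[np.ndarray]) -> None:
    """Reverse-mode sweep from several roots at once (shared tape)."""
    topo: list[Tensor] = []
    seen: set[int] = set()

    def visit(t: Tensor) -> None:
        stack = [(t, iter(t._parents))]
        if id(t) in seen:
            return
        seen.add(id(t))
        while stack:
            node, it = stack[-1]
            advanced = False
            for p in it:
                if id(p) not in seen:
                    seen.add(id(p))
                    stack.append((p, iter(p._parents)))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack.pop()

    for o in outputs:
        visit(o)
    for o, g in zip(outputs, grads):
        _accumulate(o, np.asarray(g, dtype=np.float32))
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if any(isinstance(p, Tensor) and (p.requires_grad or p._parents) for p in parents):
        out.requires_grad = True
        out._parents = tuple(p for p in parents if isinstance(p, Tensor))
        out._backward = backward_fn
    return out


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------

def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b):
    if isinstance(a, ShapeProbe):
        return a
    data = a.data + b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), bwd)


def mul(a, b):
    if isinstance(a, ShapeProbe):
        return a
    data = a.data * b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), bwd)


def cat(xs: Sequence, axis: int = 1):
    if isinstance(xs[0], ShapeProbe):
        shape = list(xs[0].shape)
        shape[axis] = sum(x.shape[axis] for x in xs)
        return xs[0].like(shape)
    data = np.concatenate([x.data for x in xs], axis=axis)
    sizes = [x.data.shape[axis] for x in xs]

    def bwd(g):
        start = 0
        for x, s in zip(xs, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            _accumulate(x, g[tuple(sl)])
            start += s

    return _make(data, tuple(xs), bwd)


def narrow(x, axis: int, start: int, length: int):
    if isinstance(x, ShapeProbe):
        shape = list(x.shape)
        shape[axis] = length
        return x.like(shape)
    sl = [slice(None)] * x.data.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    data = x.data[sl]

    def bwd(g):
        full = np.zeros_like(x.data)
        full[sl] = g
        _accumulate(x, full)

    return _make(data, (x,), bwd)


def channel_mean(x):
    """Per-pixel mean over channels -> (B, 1, H, W)."""
    if isinstance(x, ShapeProbe):
        return x.like((x.shape[0], 1, x.shape[2], x.shape[3]))
    c = x.data.shape[1]
    data = x.data.mean(axis=1, keepdims=True)

    def bwd(g):
        _accumulate(x, np.broadcast_to(g / c, x.data.shape))

    return _make(data, (x,), bwd)


def channel_max(x):
    """Per-pixel max over channels -> (B, 1, H, W)."""
    if isinstance(x, ShapeProbe):
        return x.like((x.shape[0], 1, x.shape[2], x.shape[3]))
    idx = x.data.argmax(axis=1, keepdims=True)
    data = np.take_along_axis(x.data, idx, axis=1)

    def bwd(g):
        full = np.zeros_like(x.data)
        np.put_along_axis(full, idx, g, axis=1)
        _accumulate(x, full)

    return _make(data, (x,), bwd)


def scalar_bias(x, b):
    """Add a 0-d learnable offset to a feature map."""
    if isinstance(x, ShapeProbe):
        return x

    data = x.data + b.data

    def bwd(g):
        _accumulate(x, g)
        _accumulate(b, np.array(g.sum(), dtype=np.float32))

    return _make(data, (x, b), bwd)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class; children are discovered by attribute walking."""

    def __init__(self):
        self.training = True

    def modules(self) -> Iterable["Module"]:
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def _own_tensors(self) -> Iterable[Tensor]:
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Tensor):
                        yield item

    def parameters(self, trainable_only: bool = False) -> Iterable[Tensor]:
        for m in self.modules():
            for t in m._own_tensors():
                if trainable_only and not t.requires_grad:
                    continue
                yield t

    def param_count(self, trainable_only: bool = False) -> int:
        return int(sum(t.data.size for t in self.parameters(trainable_only)))

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for t in self.parameters():
            t.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _conv_out_side(size: int, k: int, stride: int, padding: int, dilation: int) -> int:
    return (size + 2 * padding - dilation * (k - 1) - 1) // stride + 1


class Conv2d(Module):
    """Grouped, dilated 2-D cross-correlation via im2col.

    Shape-preserving padding ``dilation*(k-1)//2`` is the default, matching
    every stride-1 block in the detector.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int | None = None, dilation: int = 1,
                 groups: int = 1, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.dilation = dilation
        self.groups = groups
        self.padding = dilation * (kernel_size - 1) // 2 if padding is None else padding
        rng = rng or np.random.default_rng()
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        bound = 1.0 / math.sqrt(fan_in)
        self.weight = Tensor(
            rng.uniform(-bound, bound,
                        (out_channels, in_channels // groups, kernel_size, kernel_size)),
            requires_grad=True)
        self.bias = Tensor(rng.uniform(-bound, bound, (out_channels,)),
                           requires_grad=True) if bias else None

    # -- im2col helpers ----------------------------------------------------
    def _cols(self, xd: np.ndarray) -> np.ndarray:
        k, d, s, p = self.kernel_size, self.dilation, self.stride, self.padding
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p))) if p else xd
        span = d * (k - 1) + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, (span, span), axis=(2, 3))
        win = win[:, :, ::s, ::s, ::d, ::d]
        return win  # (B, C, Ho, Wo, k, k)

    def forward(self, x):
        k, g = self.kernel_size, self.groups
        if isinstance(x, ShapeProbe):
            b, c, h, w = x.shape
            if c != self.in_channels:
                raise ValueError(
                    f"expected {self.in_channels} input channels, got {c}")
            ho = _conv_out_side(h, k, self.stride, self.padding, self.dilation)
            wo = _conv_out_side(w, k, self.stride, self.padding, self.dilation)
            macs = b * self.out_channels * ho * wo * (self.in_channels // g) * k * k
            x.counter["flops"] += 2 * macs
            return x.like((b, self.out_channels, ho, wo))

        xd = x.data
        if xd.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {xd.shape[1]}")
        b = xd.shape[0]
        cols = self._cols(xd)
        ho, wo = cols.shape[2], cols.shape[3]
        cg = self.in_channels // g
        og = self.out_channels // g
        colsg = cols.reshape(b, g, cg, ho, wo, k, k)
        wg = self.weight.data.reshape(g, og, cg, k, k)
        out = np.einsum("bgchwij,gocij->bgohw", colsg, wg, optimize=True)
        out = out.reshape(b, self.out_channels, ho, wo)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None, None]

        conv = self

        def bwd(grad):
            go = grad.reshape(b, g, og, ho, wo)
            if conv.weight.requires_grad or True:
                gw = np.einsum("bgchwij,bgohw->gocij", colsg, go, optimize=True)
                _accumulate(conv.weight, gw.reshape(conv.weight.data.shape))
            if conv.bias is not None:
                _accumulate(conv.bias, grad.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                gcols = np.einsum("gocij,bgohw->bgchwij", wg, go, optimize=True)
                gcols = gcols.reshape(b, conv.in_channels, ho, wo, k, k)
                p, s, d = conv.padding, conv.stride, conv.dilation
                hp, wp = xd.shape[2] + 2 * p, xd.shape[3] + 2 * p
                gx = np.zeros((b, conv.in_channels, hp, wp), dtype=np.float32)
                for i in range(k):
                    for j in range(k):
                        gx[:, :, i * d:i * d + s * ho:s, j * d:j * d + s * wo:s] += gcols[..., i, j]
                if p:
                    gx = gx[:, :, p:-p, p:-p]
                _accumulate(x, gx)

        parents = (x, self.weight) + ((self.bias,) if self.bias is not None else ())
        return _make(out, parents, bwd)


class BatchNorm2d(Module):
    """Affine batch normalization (2 learnable parameters per channel)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.03):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        if isinstance(x, ShapeProbe):
            return x
        xd = x.data
        if self.training:
            mean = xd.mean(axis=(0, 2, 3))
            var = xd.var(axis=(0, 2, 3))
            n = xd.shape[0] * xd.shape[2] * xd.shape[3]
            self.running_mean += self.momentum * (mean - self.running_mean)
            unbiased = var * n / max(n - 1, 1)
            self.running_var += self.momentum * (unbiased - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (xd - mean[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        bn = self
        training = self.training

        def bwd(g):
            _accumulate(bn.gamma, (g * xhat).sum(axis=(0, 2, 3)))
            _accumulate(bn.beta, g.sum(axis=(0, 2, 3)))
            if x.requires_grad or x._parents:
                gi = g * bn.gamma.data[None, :, None, None]
                if training:
                    n = g.shape[0] * g.shape[2] * g.shape[3]
                    gxh_sum = gi.sum(axis=(0, 2, 3))
                    gxh_dot = (gi * xhat).sum(axis=(0, 2, 3))
                    gx = (gi - (gxh_sum[None, :, None, None]
                                + xhat * gxh_dot[None, :, None, None]) / n)
                    gx *= inv[None, :, None, None]
                else:
                    gx = gi * inv[None, :, None, None]
                _accumulate(x, gx)

        return _make(out, (x, self.gamma, self.beta), bwd)


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class SiLU(Module):
    def forward(self, x):
        if isinstance(x, ShapeProbe):
            return x
        s = _stable_sigmoid(x.data)
        out = x.data * s

        def bwd(g):
            _accumulate(x, g * (s * (1.0 + x.data * (1.0 - s))))

        return _make(out, (x,), bwd)


class ReLU(Module):
    def forward(self, x):
        if isinstance(x, ShapeProbe):
            return x
        mask = x.data > 0
        out = np.where(mask, x.data, 0.0)

        def bwd(g):
            _accumulate(x, g * mask)

        return _make(out, (x,), bwd)


class Sigmoid(Module):
    def forward(self, x):
        if isinstance(x, ShapeProbe):
            return x
        s = _stable_sigmoid(x.data)

        def bwd(g):
            _accumulate(x, g * s * (1.0 - s))

        return _make(s, (x,), bwd)


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    """Stride-1 (by default) shape-preserving max pooling with -inf padding."""

    def __init__(self, kernel_size: int, stride: int = 1, padding: int | None = None):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding

    def forward(self, x):
        k, s, p = self.kernel_size, self.stride, self.padding
        if isinstance(x, ShapeProbe):
            b, c, h, w = x.shape
            ho = _conv_out_side(h, k, s, p, 1)
            wo = _conv_out_side(w, k, s, p, 1)
            return x.like((b, c, ho, wo))
        xd = x.data
        xp = np.pad(xd, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else xd
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        b, c, ho, wo = win.shape[:4]
        flat = win.reshape(b, c, ho, wo, k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

        def bwd(g):
            gp = np.zeros_like(xp, dtype=np.float32)
            di, dj = idx // k, idx % k
            bi, ci, ii, ji = np.indices((b, c, ho, wo), sparse=False)
            np.add.at(gp, (bi, ci, ii * s + di, ji * s + dj), g)
            _accumulate(x, gp[:, :, p:xp.shape[2] - p, p:xp.shape[3] - p] if p else gp)

        return _make(out, (x,), bwd)


class Upsample(Module):
    """Nearest-neighbour integer-factor upsampling."""

    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        f = self.scale
        if isinstance(x, ShapeProbe):
            b, c, h, w = x.shape
            return x.like((b, c, h * f, w * f))
        out = x.data.repeat(f, axis=2).repeat(f, axis=3)
        b, c, h, w = x.data.shape

        def bwd(g):
            _accumulate(x, g.reshape(b, c, h, f, w, f).sum(axis=(3, 5)))

        return _make(out, (x,), bwd)


class SGD:
    """Plain SGD with momentum and decoupled L2 weight decay."""

    def __init__(self, params: Iterable[Tensor], lr: float = 0.01,
                 momentum: float = 0.937, weight_decay: float = 0.0005):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
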