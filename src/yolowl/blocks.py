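"""Standard detector building blocks with exact parameter-count contracts.

Every block here comes with a closed-form parameter count
(:func:`conv_param_count`) that is independent of construction, so built
modules can be audited against the layer manifest row by row.

Conventions (required to reproduce the manifest's printed counts):

* a convolution followed by batch normalization carries no bias;
* batch normalization is affine (2 parameters per channel);
* the default activation is SiLU;
* GCBS (group convolution + BN + SiLU) uses ``groups = gcd(in, out)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = [
    "ConvSpec",
    "conv_param_count",
    "gcbs_groups",
    "ConvBlock",
    "make_conv_block",
    "GCBS",
    "Bottleneck",
    "C2f",
    "SPPF",
    "c2f_param_count",
    "sppf_param_count",
]

_ACTS = {"silu": nn.SiLU, "relu": nn.ReLU, "sigmoid": nn.Sigmoid, "none": nn.Identity}


@dataclass(frozen=True)
class ConvSpec:
    """Declarative description of one convolution (+ optional BN + activation)."""

    in_channels: int
    out_channels: int
    kernel: int = 3
    stride: int = 1
    groups: int = 1
    dilation: int = 1
    has_bias: bool = False
    has_bn: bool = True
    activation: str = "silu"

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise ValueError("channel counts must be positive")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ValueError(
                f"groups={self.groups} does not divide channels "
                f"({self.in_channels}->{self.out_channels})")
        if self.activation not in _ACTS:
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def padding(self) -> int:
        return self.dilation * (self.kernel - 1) // 2


def conv_param_count(spec: ConvSpec) -> int:
    """Closed-form trainable-parameter count of a ConvSpec.

    ``(in/groups) * out * k^2`` weights, plus ``out`` if biased, plus
    ``2*out`` if batch-normalized. Pure arithmetic; no model is built.
    """
    p = (spec.in_channels // spec.groups) * spec.out_channels * spec.kernel ** 2
    if spec.has_bias:
        p += spec.out_channels
    if spec.has_bn:
        p += 2 * spec.out_channels
    return p


def gcbs_groups(in_channels: int, out_channels: int) -> int:
    """Grouping rule of the GCBS stem/downsample blocks: gcd(in, out)."""
    if in_channels < 1 or out_channels < 1:
        raise ValueError("channel counts must be positive")
    return math.gcd(in_channels, out_channels)


class ConvBlock(nn.Module):
    """Conv -> (BN) -> activation, realizing a :class:`ConvSpec`."""

    def __init__(self, spec: ConvSpec, rng: np.random.Generator | None = None):
        super().__init__()
        self.spec = spec
        self.conv = nn.Conv2d(
            spec.in_channels, spec.out_channels, spec.kernel, stride=spec.stride,
            dilation=spec.dilation, groups=spec.groups, bias=spec.has_bias, rng=rng)
        self.bn = nn.BatchNorm2d(spec.out_channels) if spec.has_bn else nn.Identity()
        self.act = _ACTS[spec.activation]()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


def make_conv_block(spec: ConvSpec, rng: np.random.Generator | None = None) -> ConvBlock:
    return ConvBlock(spec, rng=rng)


def GCBS(in_channels: int, out_channels: int, kernel: int = 3, stride: int = 2,
         rng: np.random.Generator | None = None) -> ConvBlock:
    """Group conv + batch norm + SiLU with the gcd grouping rule."""
    return ConvBlock(ConvSpec(in_channels, out_channels, kernel, stride,
                              groups=gcbs_groups(in_channels, out_channels)), rng=rng)


def _cbs(cin, cout, k=1, s=1, rng=None, act="silu"):
    return ConvBlock(ConvSpec(cin, cout, k, s, activation=act), rng=rng)


class Bottleneck(nn.Module):
    """Two 3x3 conv-BN-SiLU layers with an additive shortcut."""

    def __init__(self, channels: int, shortcut: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cv1 = _cbs(channels, channels, 3, rng=rng)
        self.cv2 = _cbs(channels, channels, 3, rng=rng)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return nn.add(y, x) if self.shortcut else y


class C2f(nn.Module):
    """Cross-stage partial block with ``n`` bottlenecks.

    1x1 split conv to ``2*hidden`` channels, a chain of bottlenecks on the
    second half (each appending its output), and a 1x1 merge conv from
    ``(2+n)*hidden`` back to ``out_channels``.
    """

    def __init__(self, in_channels: int, out_channels: int, n: int = 1,
                 shortcut: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        if out_channels % 2:
            raise ValueError("out_channels must be even")
        self.hidden = out_channels // 2
        self.cv1 = _cbs(in_channels, 2 * self.hidden, 1, rng=rng)
        self.units = [Bottleneck(self.hidden, shortcut, rng=rng) for _ in range(n)]
        self.cv2 = _cbs((2 + n) * self.hidden, out_channels, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        parts = [nn.narrow(y, 1, 0, self.hidden),
                 nn.narrow(y, 1, self.hidden, self.hidden)]
        for unit in self.units:
            parts.append(unit(parts[-1]))
        return self.cv2(nn.cat(parts, axis=1))


def c2f_param_count(in_channels: int, out_channels: int, n: int = 1) -> int:
    """Closed-form count for the stock C2f block (oracle for the audit)."""
    h = out_channels // 2
    p = conv_param_count(ConvSpec(in_channels, 2 * h, 1))
    p += n * 2 * conv_param_count(ConvSpec(h, h, 3))
    p += conv_param_count(ConvSpec((2 + n) * h, out_channels, 1))
    return p


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): 1x1 reduce to in/2, three chained
    stride-1 max pools, concat of the four streams, 1x1 expand."""

    def __init__(self, in_channels: int, out_channels: int, pool_k: int = 5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if pool_k % 2 == 0:
            raise ValueError("pool kernel must be odd")
        h = in_channels // 2
        self.cv1 = _cbs(in_channels, h, 1, rng=rng)
        self.pool = nn.MaxPool2d(pool_k)
        self.cv2 = _cbs(4 * h, out_channels, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        p1 = self.pool(y)
        p2 = self.pool(p1)
        p3 = self.pool(p2)
        return self.cv2(nn.cat([y, p1, p2, p3], axis=1))


def sppf_param_count(in_channels: int, out_channels: int) -> int:
    h = in_channels // 2
    return (conv_param_count(ConvSpec(in_channels, h, 1))
            + conv_param_count(ConvSpec(4 * h, out_channels, 1)))
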