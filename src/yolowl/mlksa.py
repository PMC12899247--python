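"""Multi-Scale Large Kernel Spatial Attention (MLKSA).

Channel statistics (per-pixel mean and max) are pushed through five
parallel large-kernel convolutions (5/7/9/11/13 by default) whose
receptive fields tile the typical size range of aerial wildlife targets,
fused by 1x1 and 3x3 convolutions, and squashed by a sigmoid into a
single-channel spatial gate in [0, 1] that multiplies the input.

Because the very first operation collapses the input to two channels, the
block's parameter count is independent of the input width — the layer
manifest lists the same 990 parameters at 32, 64 and 128 channels.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .blocks import ConvBlock, ConvSpec, conv_param_count

__all__ = ["DEFAULT_KERNELS", "channel_pool", "MLKSA", "mlksa_param_count",
           "attention_to_image"]

DEFAULT_KERNELS = (5, 7, 9, 11, 13)


def _validate_kernels(kernels) -> tuple:
    ks = tuple(kernels)
    if not ks:
        raise ValueError("kernel list must not be empty")
    if any(k % 2 == 0 for k in ks) or list(ks) != sorted(set(ks)):
        raise ValueError("kernels must be odd and strictly increasing")
    return ks


def channel_pool(x):
    """Stack per-pixel channel mean and channel max -> (B, 2, H, W)."""
    return nn.cat([nn.channel_mean(x), nn.channel_max(x)], axis=1)


class MLKSA(nn.Module):
    """Spatial attention gate; channel-preserving (output = input ⊙ gate).

    Parameter placement (reproducing the manifest's printed 990): branch
    convolutions are bias-free with BN; the two fusion convolutions carry
    bias and BN; the final 1x1 logit conv carries bias only. ReLU is used
    inside the block, sigmoid at the gate.
    """

    def __init__(self, channels: int, kernels=DEFAULT_KERNELS,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.kernels = _validate_kernels(kernels)
        self.branches = [
            ConvBlock(ConvSpec(2, 1, k, has_bn=True, has_bias=False,
                               activation="relu"), rng=rng)
            for k in self.kernels]
        nb = len(self.kernels)
        self.fuse1 = ConvBlock(ConvSpec(nb, nb, 1, has_bn=True, has_bias=True,
                                        activation="relu"), rng=rng)
        self.fuse2 = ConvBlock(ConvSpec(nb, 1, 3, has_bn=True, has_bias=True,
                                        activation="relu"), rng=rng)
        self.logit = nn.Conv2d(1, 1, 1, bias=True, rng=rng)
        self.sigmoid = nn.Sigmoid()

    def attention(self, x):
        """The spatial weight map A ∈ [0,1]^(B x 1 x H x W)."""
        z = channel_pool(x)
        f = nn.cat([b(z) for b in self.branches], axis=1)
        f = self.fuse2(self.fuse1(f))
        return self.sigmoid(self.logit(f))

    def forward(self, x):
        return nn.mul(x, self.attention(x))


def mlksa_param_count(channels: int, kernels=DEFAULT_KERNELS) -> int:
    """Closed-form count; ``channels`` is accepted for interface symmetry
    but does not influence the result."""
    ks = _validate_kernels(kernels)
    nb = len(ks)
    p = sum(conv_param_count(ConvSpec(2, 1, k, has_bn=True, has_bias=False))
            for k in ks)
    p += conv_param_count(ConvSpec(nb, nb, 1, has_bn=True, has_bias=True))
    p += conv_param_count(ConvSpec(nb, 1, 3, has_bn=True, has_bias=True))
    p += 2  # final 1x1 logit conv: 1 weight + 1 bias
    return p


def attention_to_image(attention) -> np.ndarray:
    """Render an attention map as a uint8 grayscale image (inspection aid)."""
    a = attention.data if isinstance(attention, nn.Tensor) else np.asarray(attention)
    a = a[0, 0]
    return np.clip(a * 255.0, 0, 255).astype(np.uint8)
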