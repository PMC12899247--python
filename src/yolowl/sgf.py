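"""Spatial Guidance Fusion (SGF) junctions of the shallow neck.

Each incoming pyramid feature is spatially re-weighted before fusion: a
(mean, max) channel descriptor of the input is pushed through a 5x5 gate
convolution shared across all inputs, the two gate channels are summed,
a per-input scalar bias is added, and a sigmoid yields that input's gate
in [0, 1]. Gated inputs are concatenated along channels.

Sharing the gate convolution and keeping only the scalar bias per input
gives the parameter count 100 + n, reproducing both printed manifest
values: 102 for the two-input junction (SGF-2) and 103 for the
three-input one (SGF-3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .mlksa import channel_pool

__all__ = ["SGFConfig", "SGF", "sgf_param_count"]


@dataclass(frozen=True)
class SGFConfig:
    n_inputs: int = 2
    gate_kernel: int = 5
    gate_bias: bool = False          # bias of the shared gate conv itself

    def __post_init__(self):
        if not 2 <= self.n_inputs <= 3:
            raise ValueError("SGF fuses 2 or 3 inputs")
        if self.gate_kernel % 2 == 0:
            raise ValueError("gate kernel must be odd")


class SGF(nn.Module):
    """Gated concatenation of 2 or 3 equal-resolution feature maps."""

    def __init__(self, cfg: SGFConfig = SGFConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        # shared 2->2 gate conv; channel-summed afterwards
        self.gate_conv = nn.Conv2d(2, 2, cfg.gate_kernel, bias=cfg.gate_bias, rng=rng)
        self.input_bias = [nn.Tensor(np.zeros(()), requires_grad=True)
                           for _ in range(cfg.n_inputs)]
        self.sigmoid = nn.Sigmoid()

    def gates(self, inputs):
        """Per-input spatial gate maps, each (B, 1, H, W) in [0, 1]."""
        out = []
        for i, x in enumerate(inputs):
            g = self.gate_conv(channel_pool(x))
            g = nn.add(nn.narrow(g, 1, 0, 1), nn.narrow(g, 1, 1, 1))
            g = nn.scalar_bias(g, self.input_bias[i])
            out.append(self.sigmoid(g))
        return out

    def forward(self, inputs):
        if len(inputs) != self.cfg.n_inputs:
            raise ValueError(
                f"expected {self.cfg.n_inputs} inputs, got {len(inputs)}")
        shapes = {tuple(x.shape[2:]) for x in inputs}
        if len(shapes) != 1:
            raise ValueError(f"mismatched spatial shapes: {sorted(shapes)}")
        if isinstance(inputs[0], nn.ShapeProbe):
            # gate convs contribute FLOPs even in probe mode
            for x in inputs:
                self.gate_conv(channel_pool(x))
            return nn.cat(inputs, axis=1)
        gated = [nn.mul(x, g) for x, g in zip(inputs, self.gates(inputs))]
        return nn.cat(gated, axis=1)


def sgf_param_count(n_inputs: int, gate_kernel: int = 5,
                    gate_bias: bool = False) -> int:
    """2*2*k^2 shared gate weights (+optional bias pair) + n scalar biases."""
    return 2 * 2 * gate_kernel ** 2 + (2 if gate_bias else 0) + n_inputs
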