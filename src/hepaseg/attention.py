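"""Hybrid gated attention on skip connections.

A channel-attention stream (squeeze-and-excitation style) and a spatial-
attention stream are computed in parallel from the same encoder feature
map, and a learned per-pixel gate g in (0,1) blends them convexly:

    out = (1 - g) * F_c + g * F_s

The gate consumes only the two attended maps themselves, so at every pixel
the output lies between the channel-attended and spatially-attended values.
The gate's final convolution is zero-initialized, so training starts from
the balanced g = 0.5 average of the two streams.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv2d, Module


class ChannelAttention(Module):
    """Per-channel reweighting from globally pooled statistics.

    Global average pooling -> FC (C -> C/r) -> ReLU -> FC (-> C) -> sigmoid.
    The fully connected layers are realized as 1x1 convolutions on the
    (B, C, 1, 1) pooled tensor.  ``use_max_pool=True`` adds a max-pooled
    descriptor through the same MLP (CBAM-style variant, off by default).
    """

    def __init__(self, channels: int, reduction: int = 16,
                 use_max_pool: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if channels < 1:
            raise ValueError(f"channels must be >= 1, got {channels}")
        hidden = max(1, channels // max(1, reduction))
        self.use_max_pool = use_max_pool
        self.fc1 = Conv2d(channels, hidden, kernel=1, bias=True, rng=rng)
        self.fc2 = Conv2d(hidden, channels, kernel=1, bias=True, rng=rng)

    def attention_map(self, x: Tensor) -> Tensor:
        pooled = ag.tmean(x, axis=(2, 3), keepdims=True)
        logits = self.fc2(ag.relu(self.fc1(pooled)))
        if self.use_max_pool:
            mx = ag.tmax(ag.tmax(x, axis=3, keepdims=True), axis=2,
                         keepdims=True)
            logits = logits + self.fc2(ag.relu(self.fc1(mx)))
        return ag.sigmoid(logits)

    def forward(self, x: Tensor):
        wc = self.attention_map(x)
        return wc, x * wc


class SpatialAttention(Module):
    """Per-pixel reweighting from cross-channel mean and max maps.

    Channel-wise average and max pooling give two (B,1,H,W) maps; their
    concatenation passes through a 7x7 convolution and a sigmoid.
    """

    def __init__(self, kernel: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel=kernel, bias=True, rng=rng)

    def attention_map(self, x: Tensor) -> Tensor:
        avg = ag.tmean(x, axis=1, keepdims=True)
        mx = ag.tmax(x, axis=1, keepdims=True)
        return ag.sigmoid(self.conv(ag.concat([avg, mx], axis=1)))

    def forward(self, x: Tensor):
        ws = self.attention_map(x)
        return ws, x * ws


class AttentionGate(Module):
    """Single-channel gate computed from the two attended feature maps.

    Concat(F_c, F_s) -> 1x1 conv (2C -> C) -> ReLU -> 1x1 conv (-> 1)
    -> sigmoid.  The final convolution starts at zero so the initial gate
    is exactly 0.5 everywhere.
    """

    def __init__(self, channels: int, hidden: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = channels if hidden is None else hidden
        self.reduce = Conv2d(2 * channels, hidden, kernel=1, bias=True, rng=rng)
        self.project = Conv2d(hidden, 1, kernel=1, bias=True, rng=rng)
        self.project.weight.data[...] = 0.0
        self.project.bias.data[...] = 0.0

    def forward(self, fc: Tensor, fs: Tensor) -> Tensor:
        if fc.shape != fs.shape:
            raise ValueError(
                f"attended maps must share a shape, got {fc.shape} vs "
                f"{fs.shape}")
        z = ag.relu(self.reduce(ag.concat([fc, fs], axis=1)))
        return ag.sigmoid(self.project(z))


class HybridGatedAttention(Module):
    """Convex blend of channel- and spatial-attended maps via a learned gate."""

    def __init__(self, channels: int, reduction: int = 16,
                 channel_max_pool: bool = False, gate_hidden: int | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction=reduction,
                                        use_max_pool=channel_max_pool, rng=rng)
        self.spatial = SpatialAttention(rng=rng)
        self.gate = AttentionGate(channels, hidden=gate_hidden, rng=rng)

    def forward(self, x: Tensor, return_maps: bool = False):
        wc, fc = self.channel(x)
        ws, fs = self.spatial(x)
        g = self.gate(fc, fs)
        out = (1.0 - g) * fc + g * fs
        if return_maps:
            return out, {"channel": wc, "spatial": ws, "gate": g,
                         "fc": fc, "fs": fs}
        return out


__all__ = ["ChannelAttention", "SpatialAttention", "AttentionGate",
           "HybridGatedAttention"]
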