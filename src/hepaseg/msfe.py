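"""Multi-scale feature enhancement bottleneck.

An atrous-spatial-pyramid-pooling stage with five parallel branches — a 1x1
convolution, three 3x3 depthwise-separable dilated convolutions at rates
4/8/12, and a global-average-pooling branch — concatenated and fused by a
1x1 convolution, followed by a global-context channel reweighting with an
additive skip, and a final 1x1 projection.  It replaces the double-conv
bottleneck of the classic U-Net, widening the receptive field at the
network's deepest, lowest-resolution stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, DepthwiseSeparableConv2d, Module


@dataclass
class MSFEConfig:
    in_channels: int
    branch_channels: int | None = None
    out_channels: int | None = None
    dilation_rates: tuple = (4, 8, 12)
    reweight_fused: bool = True  # False: attention consumes the raw concat

    def __post_init__(self):
        if self.branch_channels is None:
            self.branch_channels = self.in_channels
        if self.out_channels is None:
            self.out_channels = self.in_channels
        if self.branch_channels < 1:
            raise ValueError("branch_channels must be >= 1")


def effective_kernel_size(kernel: int, dilation: int) -> int:
    """Receptive extent of a dilated kernel: k + (k-1)(d-1)."""
    return kernel + (kernel - 1) * (dilation - 1)


class _BranchUnit(Module):
    """conv -> BN -> ReLU wrapper shared by the pyramid branches."""

    def __init__(self, conv: Module, channels: int):
        super().__init__()
        self.conv = conv
        self.bn = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(self.bn(self.conv(x)))


class ASPPBranches(Module):
    """Five parallel branches, concatenation, and 1x1 fusion."""

    def __init__(self, cfg: MSFEConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        cin, cb = cfg.in_channels, cfg.branch_channels
        self.local = _BranchUnit(Conv2d(cin, cb, kernel=1, bias=False, rng=rng),
                                 cb)
        self.dilated = [
            _BranchUnit(DepthwiseSeparableConv2d(cin, cb, kernel=3, dilation=d,
                                                 bias=False, rng=rng), cb)
            for d in cfg.dilation_rates
        ]
        # Global pooling branch: 1x1 conv on the pooled descriptor.  No BN
        # here: batch statistics of a 1x1 spatial map are degenerate.
        self.pool_conv = Conv2d(cin, cb, kernel=1, bias=True, rng=rng)
        n_branches = 2 + len(cfg.dilation_rates)
        self.fuse = _BranchUnit(
            Conv2d(n_branches * cb, cfg.out_channels, kernel=1, bias=False,
                   rng=rng), cfg.out_channels)

    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        _, _, h, w = x.shape
        min_hw = effective_kernel_size(3, max(self.cfg.dilation_rates)) // 2 + 1
        if min(h, w) < min_hw:
            warnings.warn(
                f"spatial dims ({h},{w}) are small for dilation rates "
                f"{self.cfg.dilation_rates}; branches are zero-padded",
                stacklevel=2)
        outs = [self.local(x)]
        outs += [branch(x) for branch in self.dilated]
        pooled = ag.tmean(x, axis=(2, 3), keepdims=True)
        pooled = ag.relu(self.pool_conv(pooled))
        outs.append(ag.broadcast_hw(pooled, h, w))
        return outs

    def forward(self, x: Tensor, return_concat: bool = False):
        cat = ag.concat(self.branch_outputs(x), axis=1)
        fused = self.fuse(cat)
        if return_concat:
            return fused, cat
        return fused


class GlobalContextReweight(Module):
    """Channel attention with additive skip: out = x * a + x.

    Attention path: global average pool -> 1x1 conv -> BN -> ReLU ->
    sigmoid, yielding a (B, C, 1, 1) map in (0,1).
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(channels, channels, kernel=1, bias=True, rng=rng)
        self.bn = BatchNorm2d(channels)

    def attention_map(self, x: Tensor) -> Tensor:
        pooled = ag.tmean(x, axis=(2, 3), keepdims=True)
        return ag.sigmoid(ag.relu(self.bn(self.conv(pooled))))

    def forward(self, x: Tensor) -> Tensor:
        return x * self.attention_map(x) + x


class MultiScaleFeatureEnhancement(Module):
    """Full bottleneck: pyramid -> reweighting -> final 1x1 projection."""

    def __init__(self, cfg: MSFEConfig, rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        self.aspp = ASPPBranches(cfg, rng=rng)
        reweight_ch = (cfg.out_channels if cfg.reweight_fused
                       else (2 + len(cfg.dilation_rates)) * cfg.branch_channels)
        self.reweight = GlobalContextReweight(reweight_ch, rng=rng)
        proj_in = cfg.out_channels if cfg.reweight_fused else reweight_ch
        self.project = Conv2d(proj_in, cfg.out_channels, kernel=1, bias=True,
                              rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.cfg.reweight_fused:
            fused = self.aspp(x)
            return self.project(self.reweight(fused))
        fused, cat = self.aspp(x, return_concat=True)
        del fused
        return self.project(self.reweight(cat))


__all__ = ["MSFEConfig", "ASPPBranches", "GlobalContextReweight",
           "MultiScaleFeatureEnhancement", "effective_kernel_size"]
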