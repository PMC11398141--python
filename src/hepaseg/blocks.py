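"""Convolutional building blocks of the encoder/decoder.

The residual modules follow the H(x) = F(x) + x decomposition: a first
conv-BN-act unit widens the input, a three-segment sequence (two activated
units around a non-activated one) learns the residual F, the two are summed,
and a final activated unit produces the block output.  Encoder blocks use
ReLU throughout; decoder blocks use ELU, which keeps gradient flowing for
negative pre-activations during detail reconstruction.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, DepthwiseSeparableConv2d, Module


def _apply_activation(x: Tensor, activation: str | None) -> Tensor:
    if activation is None:
        return x
    if activation == "relu":
        return ag.relu(x)
    if activation == "elu":
        return ag.elu(x)
    raise ValueError(f"unknown activation {activation!r}")


class ConvUnit(Module):
    """3x3 convolution + batch norm + optional activation.

    With an activation this is the 'conv1' unit; with ``activation=None``
    it is the 'conv2' unit (convolution + BN only).  The convolution
    carries no bias: BN's shift makes it redundant.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 activation: str | None = "relu", kernel: int = 3,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError(
                f"channel counts must be positive, got {in_channels} -> "
                f"{out_channels}")
        self.activation = activation
        self.conv = Conv2d(in_channels, out_channels, kernel=kernel,
                           bias=False, rng=rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return _apply_activation(self.bn(self.conv(x)), self.activation)


def conv1_unit(in_channels: int, out_channels: int, activation: str = "relu",
               rng: np.random.Generator | None = None) -> ConvUnit:
    """Conv + BN + activation unit."""
    return ConvUnit(in_channels, out_channels, activation=activation, rng=rng)


def conv2_unit(in_channels: int, out_channels: int,
               rng: np.random.Generator | None = None) -> ConvUnit:
    """Conv + BN unit with no activation."""
    return ConvUnit(in_channels, out_channels, activation=None, rng=rng)


class ResidualBlock(Module):
    """Improved residual module used in place of U-Net double convolutions.

    entry:    conv1  (in -> out)            -- also the identity/skip path
    branch:   conv1, conv2, i.e. two activated units and a final
              non-activated one (out -> out each)
    merge:    entry + branch, then a final conv1 (out -> out)

    The channel change happens in the entry unit so the skip addition is
    dimensionally valid without a projection shortcut.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 activation: str = "relu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError(
                f"channel counts must be positive, got {in_channels} -> "
                f"{out_channels}")
        a = activation
        self.entry = ConvUnit(in_channels, out_channels, a, rng=rng)
        self.branch = [
            ConvUnit(out_channels, out_channels, a, rng=rng),
            ConvUnit(out_channels, out_channels, a, rng=rng),
            ConvUnit(out_channels, out_channels, None, rng=rng),
        ]
        self.exit = ConvUnit(out_channels, out_channels, a, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        a = self.entry(x)
        b = a
        for unit in self.branch:
            b = unit(b)
        return self.exit(a + b)

    def zero_branch_(self):
        """Freeze the residual branch to the zero function (weight surgery).

        Zeroing each branch convolution and its BN affine leaves only the
        skip path; used to verify the F(x)=0 => H(x)=x degeneracy.
        """
        for unit in self.branch:
            unit.conv.weight.data[...] = 0.0
            unit.bn.gamma.data[...] = 0.0
            unit.bn.beta.data[...] = 0.0


class EncoderResidualBlock(ResidualBlock):
    """Residual block with ReLU activations (feature extraction path)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__(in_channels, out_channels, activation="relu", rng=rng)


class DecoderResidualBlock(ResidualBlock):
    """Residual block with ELU activations (detail reconstruction path)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__(in_channels, out_channels, activation="elu", rng=rng)


class DoubleConv(Module):
    """Classic U-Net stage: two conv-BN-ReLU units (the ablation baseline)."""

    def __init__(self, in_channels: int, out_channels: int,
                 activation: str = "relu",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.unit1 = ConvUnit(in_channels, out_channels, activation, rng=rng)
        self.unit2 = ConvUnit(out_channels, out_channels, activation, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.unit2(self.unit1(x))


def separable_parameter_count(in_channels: int, out_channels: int,
                              kernel: int, bias: bool = False) -> int:
    """Closed-form parameter count of a depthwise-separable convolution."""
    n = in_channels * kernel * kernel + in_channels * out_channels
    if bias:
        n += out_channels
    return n


__all__ = [
    "ConvUnit", "conv1_unit", "conv2_unit", "ResidualBlock",
    "EncoderResidualBlock", "DecoderResidualBlock", "DoubleConv",
    "DepthwiseSeparableConv2d", "separable_parameter_count",
]
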