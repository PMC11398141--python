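"""Layers, parameter containers, and the Adam optimizer.

A deliberately small `Module` system in the spirit of torch.nn: modules own
parameters (trainable `Tensor`s) and buffers (plain arrays such as
batch-norm running statistics), discover submodules by attribute scanning,
and serialize to flat name->array dictionaries.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int,
                   dtype=np.float32) -> np.ndarray:
    """He initialization (fan-in mode), suited to ReLU/ELU networks."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Module:
    """Base class: submodule discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------
    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def _own_params(self):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield name, val

    def _own_buffers(self):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield name, val

    def named_parameters(self, prefix: str = ""):
        for name, p in self._own_params():
            yield prefix + name, p
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- modes ------------------------------------------------------------
    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    # -- serialization ----------------------------------------------------
    def state_dict(self, prefix: str = "") -> dict:
        state = {}
        for name, p in self._own_params():
            state[prefix + name] = p.data
        for name, b in self._own_buffers():
            state[prefix + name] = b
        for cname, child in self._children():
            state.update(child.state_dict(prefix + cname + "."))
        return state

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, p in self._own_params():
            p.data = np.asarray(state[prefix + name], dtype=p.data.dtype)
        for name, _ in list(self._own_buffers()):
            setattr(self, name, np.asarray(state[prefix + name]))
        for cname, child in self._children():
            child.load_state_dict(state, prefix + cname + ".")

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Stride-1 square convolution with optional dilation; 'same' padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels < 1 or out_channels < 1:
            raise ValueError(
                f"channel counts must be positive, got {in_channels} -> "
                f"{out_channels}")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        fan_in = in_channels * kernel * kernel
        self.weight = Tensor(
            kaiming_normal(rng, (out_channels, in_channels, kernel, kernel),
                           fan_in), requires_grad=True)
        self.bias = (Tensor(np.zeros(out_channels, dtype=np.float32),
                            requires_grad=True) if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, dilation=self.dilation)


class DepthwiseSeparableConv2d(Module):
    """Per-channel spatial convolution + 1x1 pointwise channel mixing.

    Parameter count (bias-free): C_in*k^2 + C_in*C_out, versus
    C_in*C_out*k^2 for a dense convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 dilation: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"even kernel size {kernel} is unsupported")
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.dilation = dilation
        self.depthwise = Tensor(
            kaiming_normal(rng, (in_channels, kernel, kernel),
                           kernel * kernel), requires_grad=True)
        self.pointwise = Tensor(
            kaiming_normal(rng, (out_channels, in_channels, 1, 1),
                           in_channels), requires_grad=True)
        self.bias = (Tensor(np.zeros(out_channels, dtype=np.float32),
                            requires_grad=True) if bias else None)

    def forward(self, x: Tensor) -> Tensor:
        y = ag.depthwise_conv2d(x, self.depthwise, dilation=self.dilation)
        return ag.conv2d(y, self.pointwise, self.bias)


class ConvTranspose2d(Module):
    """2x2 stride-2 transposed convolution (doubles H and W)."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Tensor(
            kaiming_normal(rng, (in_channels, out_channels, 2, 2),
                           in_channels * 4), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32),
                           requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose2d_2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    """Batch normalization over (B, H, W) per channel."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Tensor(np.ones((1, channels, 1, 1), dtype=np.float32),
                            requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1, 1), dtype=np.float32),
                           requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1, 1), dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            out, mu, var = ag.batchnorm2d(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean
                                 + m * mu.astype(np.float32))
            self.running_var = ((1 - m) * self.running_var
                                + m * var.astype(np.float32))
            return out
        inv = (1.0 / np.sqrt(self.running_var + self.eps)).astype(x.dtype)
        scale = self.gamma.data.astype(x.dtype) * inv
        shift = (self.beta.data
                 - self.gamma.data * self.running_mean * inv).astype(x.dtype)
        return x * scale + shift


class MaxPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.maxpool2d_2x2(x)


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(x.dtype)
        return x * (keep / (1.0 - self.p))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with decoupled weight decay (AdamW-style L2 regularization)."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            update = (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
            if self.weight_decay:
                p.data = p.data - self.lr * self.weight_decay * p.data
            p.data = p.data - self.lr * update
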