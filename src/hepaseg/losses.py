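"""Dice, binary cross-entropy, and their weighted compound loss.

Dice loss measures region overlap and is insensitive to the foreground/
background imbalance typical of lesion segmentation, but its gradients
blow up when both the target and the prediction are tiny; BCE supplies
stable per-pixel gradients.  The compound loss blends them:

    L = alpha * BCE + (1 - alpha) * Dice,   alpha = 0.5 by default.

Inputs may be `Tensor`s (differentiable) or plain arrays.  Predictions and
targets are interpreted as (B, C, ...) with losses computed per channel and
averaged, so the liver and tumor channels carry equal weight; 1-D inputs
are treated as a single channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor


@dataclass
class LossConfig:
    alpha: float = 0.5      # BCE weight in the compound loss
    epsilon: float = 1e-5   # Dice smoothing constant
    clip: float = 1e-7      # probability floor/ceiling for the BCE logs

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 < self.clip < 0.5:
            raise ValueError("clip must be in (0, 0.5)")


def _as_bc(t) -> Tensor:
    """Coerce to a Tensor flattened to (B*C, N) channel rows."""
    t = t if isinstance(t, Tensor) else Tensor(np.asarray(t, dtype=np.float64))
    if t.ndim <= 1:
        return ag.reshape(t, (1, -1))
    b, c = t.shape[0], t.shape[1]
    return ag.reshape(t, (b * c, -1))


def _check_shapes(x, y):
    xs = np.shape(x.data if isinstance(x, Tensor) else x)
    ys = np.shape(y.data if isinstance(y, Tensor) else y)
    if xs != ys:
        raise ValueError(f"prediction shape {xs} != target shape {ys}")


def dice_loss(x, y, epsilon: float = 1e-5) -> Tensor:
    """1 - (2*sum(xy) + eps) / (sum(x) + sum(y) + eps), per channel row."""
    _check_shapes(x, y)
    xr, yr = _as_bc(x), _as_bc(y)
    inter = ag.tsum(xr * yr, axis=1)
    denom = ag.tsum(xr, axis=1) + ag.tsum(yr, axis=1)
    dice = (2.0 * inter + epsilon) / (denom + epsilon)
    return ag.tmean(1.0 - dice)


def bce_loss(x, y, clip: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy with probabilities clipped away from 0/1."""
    _check_shapes(x, y)
    xr, yr = _as_bc(x), _as_bc(y)
    xc = ag.clip(xr, clip, 1.0 - clip)
    ll = yr * ag.log(xc) + (1.0 - yr) * ag.log(1.0 - xc)
    return -ag.tmean(ll)


def bce_dice_loss(x, y, cfg: LossConfig | None = None) -> Tensor:
    cfg = cfg or LossConfig()
    b = bce_loss(x, y, clip=cfg.clip)
    d = dice_loss(x, y, epsilon=cfg.epsilon)
    return cfg.alpha * b + (1.0 - cfg.alpha) * d


__all__ = ["LossConfig", "dice_loss", "bce_loss", "bce_dice_loss"]
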