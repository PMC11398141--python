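"""Assembly of the segmentation network and its ablation variants.

A 4-level encoder/decoder U-Net skeleton in which (independently
toggleable):

* ``use_residual`` replaces each stage's double convolution with the
  improved residual module (ReLU flavor in the encoder, ELU in the decoder);
* ``use_hga`` passes each encoder skip through hybrid gated attention
  before concatenation with the upsampled decoder feature;
* ``use_msfe`` replaces the bottleneck double convolution with the
  multi-scale feature enhancement module.

With all three flags off the network is a vanilla U-Net, the ablation
baseline.  The head is a 1x1 convolution to two independent sigmoid
channels (liver, tumor), matching the binary Dice/BCE loss formulation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor, no_grad
from .blocks import DecoderResidualBlock, DoubleConv, EncoderResidualBlock
from .attention import HybridGatedAttention
from .msfe import MSFEConfig, MultiScaleFeatureEnhancement
from .nn import Conv2d, ConvTranspose2d, Dropout, MaxPool2d, Module

LIVER_CHANNEL = 0
TUMOR_CHANNEL = 1


@dataclass
class NetworkConfig:
    in_channels: int = 3          # 2.5D stack: slice below / target / above
    num_classes: int = 2          # liver, tumor (independent sigmoid heads)
    base_width: int = 64
    depth: int = 4
    use_residual: bool = True
    use_hga: bool = True
    use_msfe: bool = True
    dropout_rate: float = 0.2
    hga_reduction: int = 16

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError(f"depth must be >= 1, got {self.depth}")
        if self.base_width < 1:
            raise ValueError(f"base_width must be >= 1, got {self.base_width}")


@dataclass
class SegmentationOutput:
    logits: Tensor         # (B, num_classes, H, W), unconstrained
    probabilities: Tensor  # sigmoid(logits), elementwise in (0,1)


ABLATION_GRID = (
    ("U-Net", dict(use_residual=False, use_hga=False, use_msfe=False)),
    ("U-Net+Res", dict(use_residual=True, use_hga=False, use_msfe=False)),
    ("U-Net+HGA", dict(use_residual=False, use_hga=True, use_msfe=False)),
    ("U-Net+MSFE", dict(use_residual=False, use_hga=False, use_msfe=True)),
    ("U-Net+Res+HGA", dict(use_residual=True, use_hga=True, use_msfe=False)),
    ("Full", dict(use_residual=True, use_hga=True, use_msfe=True)),
)


class SegmentationNetwork(Module):
    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        widths = [cfg.base_width * 2 ** i for i in range(cfg.depth)]
        bottleneck_width = cfg.base_width * 2 ** cfg.depth

        enc_block = (EncoderResidualBlock if cfg.use_residual
                     else lambda i, o, rng=None: DoubleConv(i, o, "relu",
                                                            rng=rng))
        dec_block = (DecoderResidualBlock if cfg.use_residual
                     else lambda i, o, rng=None: DoubleConv(i, o, "elu",
                                                            rng=rng))

        self.encoders = []
        prev = cfg.in_channels
        for w in widths:
            self.encoders.append(enc_block(prev, w, rng=rng))
            prev = w
        self.pool = MaxPool2d()

        if cfg.use_msfe:
            self.bottleneck = MultiScaleFeatureEnhancement(
                MSFEConfig(in_channels=prev, branch_channels=prev,
                           out_channels=bottleneck_width), rng=rng)
        else:
            self.bottleneck = DoubleConv(prev, bottleneck_width, "relu",
                                         rng=rng)

        if cfg.use_hga:
            self.skip_attention = [
                HybridGatedAttention(w, reduction=cfg.hga_reduction, rng=rng)
                for w in widths
            ]
        else:
            self.skip_attention = []

        self.upsamplers = []
        self.decoders = []
        prev = bottleneck_width
        for w in reversed(widths):
            self.upsamplers.append(ConvTranspose2d(prev, w, rng=rng))
            self.decoders.append(dec_block(2 * w, w, rng=rng))
            prev = w

        # regularization after the bottleneck and the two deepest decoders
        self.dropouts = [Dropout(cfg.dropout_rate, np.random.default_rng(
            rng.integers(2 ** 31))) for _ in range(3)]
        self.head = Conv2d(prev, cfg.num_classes, kernel=1, bias=True, rng=rng)

    def forward(self, x) -> SegmentationOutput:
        x = x if isinstance(x, Tensor) else Tensor(x)
        _, _, h, w = x.shape
        mult = 2 ** self.cfg.depth
        if h % mult or w % mult:
            raise ValueError(
                f"input spatial dims ({h},{w}) must be divisible by "
                f"{mult} (2^depth)")
        skips = []
        for enc in self.encoders:
            x = enc(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        x = self.dropouts[0](x)
        for i, (up, dec) in enumerate(zip(self.upsamplers, self.decoders)):
            skip = skips[-(i + 1)]
            if self.cfg.use_hga:
                skip = self.skip_attention[len(self.encoders) - 1 - i](skip)
            x = up(x)
            x = dec(ag.concat([skip, x], axis=1))
            if i < 2:
                x = self.dropouts[i + 1](x)
        logits = self.head(x)
        return SegmentationOutput(logits=logits,
                                  probabilities=ag.sigmoid(logits))

    def predict(self, x) -> np.ndarray:
        """Inference-mode probabilities as a NumPy array."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(x)
        finally:
            if was_training:
                self.train()
        return out.probabilities.data


def build_network(cfg: NetworkConfig, seed: int = 0) -> SegmentationNetwork:
    return SegmentationNetwork(cfg, seed=seed)


def predict_masks(out: SegmentationOutput | np.ndarray,
                  threshold: float = 0.5) -> dict:
    """Binarize per-channel probabilities and compose a label map.

    Returns liver/tumor boolean masks plus a composite {0,1,2} label map in
    which tumor (2) overrides liver (1) wherever both channels fire —
    lesions lie inside the liver.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    probs = (out.probabilities.data if isinstance(out, SegmentationOutput)
             else np.asarray(out))
    liver = probs[:, LIVER_CHANNEL] >= threshold
    tumor = probs[:, TUMOR_CHANNEL] >= threshold
    labels = np.zeros(liver.shape, dtype=np.uint8)
    labels[liver] = 1
    labels[tumor] = 2
    return {"liver": liver, "tumor": tumor, "labels": labels}


def save_checkpoint(path, model: SegmentationNetwork, extra: dict | None = None):
    """Serialize weights + config + seed to a single .npz archive."""
    meta = {"config": asdict(model.cfg), "seed": model.seed,
            "extra": extra or {}}
    state = {f"param::{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[SegmentationNetwork, dict]:
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        state = {k[len("param::"):]: archive[k] for k in archive.files
                 if k.startswith("param::")}
    model = SegmentationNetwork(NetworkConfig(**meta["config"]),
                                seed=meta["seed"])
    model.load_state_dict(state)
    return model, meta
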