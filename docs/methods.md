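# Methods

This note records what the package computes, the assumptions behind it,
why the default parameters are what they are, how realistic the synthetic
data generator is, and where the numerical implementation makes
non-obvious choices.

## Model

The segmentation network is a 4-level U-Net encoder–decoder over 2.5D
inputs (3 channels: the target axial slice and its two neighbors) with two
independent sigmoid output channels (liver, tumor). Treating the two
classes as independent binary problems — rather than a 3-way softmax —
matches the compound Dice+BCE loss and makes the "tumor inside liver"
relationship a property of the data rather than a constraint of the head;
at mask-composition time the tumor channel overrides the liver channel.

Three modules can be toggled independently (the ablation grid):

* **Residual blocks** (`use_residual`). Entry unit conv-BN-act widens
  `in → out`; the residual branch stacks two activated conv-BN units and
  one non-activated unit (`out → out`); branch and entry sum; an exit unit
  finishes the block. Channel widening happens in the entry unit so the
  skip addition needs no projection shortcut. Encoder blocks use ReLU,
  decoder blocks ELU.
* **Hybrid gated attention** (`use_hga`) on each skip connection.
  Channel stream: global average pool → 1×1 (C → C/r, r = 16 by default,
  floored at 1) → ReLU → 1×1 → sigmoid, multiplied into the input.
  Spatial stream: channel mean and max maps → 7×7 conv → sigmoid,
  multiplied into the input. Gate: concat of the two attended maps →
  1×1 (2C → C) → ReLU → 1×1 (→ 1) → sigmoid; output
  `(1 − g)·F_C + g·F_S`. The gate's last convolution is zero-initialized:
  the blend starts at the neutral 0.5/0.5 average instead of an arbitrary
  random mixture, and the bounded-between-streams property holds by
  construction.
* **Multi-scale feature enhancement** (`use_msfe`) at the bottleneck.
  Five parallel branches at the deepest resolution — 1×1; three 3×3
  depthwise-separable convolutions dilated at 4/8/12 (effective extents
  9/17/25); global average pooling + 1×1 — each conv-BN-ReLU except the
  pooling branch (see "Numerical choices"), concatenated and fused by a
  1×1 conv-BN-ReLU, then reweighted by a global-context channel attention
  with additive skip (`x·a + x`), then projected 1×1. In the assembled
  network the bottleneck maps `8w → 16w` for base width `w`, mirroring
  the classic U-Net width doubling; the standalone module accepts
  arbitrary widths.

## Loss and metrics

`L = α·BCE + (1 − α)·Dice` with `α = 0.5`. Dice is computed per channel
row as `1 − (2Σxy + ε)/(Σx + Σy + ε)` with `ε = 1e−5` and averaged, so
liver and tumor carry equal weight despite their pixel-count imbalance;
BCE clips probabilities to `[1e−7, 1 − 1e−7]`. Evaluation reports Dice,
Jaccard, precision, and recall per class as percentages, aggregated
either as a mean of per-volume metrics (default; every case weighs
equally) or from pooled counts. A case with empty ground truth scores 1.0
if the prediction is also empty, else 0.0.

## Parameters and why

| Parameter | Default | Rationale |
| --- | --- | --- |
| Window width/level | 200 / 40 HU | soft-tissue window `[−60, 140]` bracketing liver parenchyma and hypodense lesions |
| CLAHE clip limit / tiles | 0.01 / 8×8 | scikit-image's fractional clip-limit convention; 8×8 tiles standard |
| α (BCE weight) | 0.5 | equal pull between pixel-stable BCE and imbalance-robust Dice |
| Dice ε | 1e−5 | keeps empty-empty channels at zero loss without biasing others |
| Optimizer | Adam (0.9, 0.999) | the standard companion of a 1e-4 initial rate; L2 as decoupled weight decay 1e−5 |
| LR schedule | lr₀·0.95^epoch | exponential per-epoch decay |
| Reference profile | 480 crops, base 64, 120 epochs, lr 1e−4 | full-scale CT configuration (GPU-scale; documented, not tested) |
| Desk profile | 96 crops, base 8, 10 epochs, lr 1e−3, 400 samples/epoch | sized from measured ~0.7 s/step so a 200-phantom study finishes in ~12 min on one CPU; the higher rate suits the much smaller network |
| Dropout | 0.2 after bottleneck and the two deepest decoder stages | regularizes where features are widest |
| Batch size | 4 | memory-bounded at reference scale; kept for the desk profile |
| Slice sampling | all liver-bearing slices + 10% of empty ones | limits trivially-negative gradients |
| Model selection | best mean(liver, tumor) validation Dice, scored each epoch on the first 8 held-out volumes | full validation each epoch costs ~25 s/volume-set and would dominate the CPU budget; final metrics always come from the complete held-out set |

## Synthetic phantoms: realism and limits

Each phantom is an axis-aligned ellipsoidal liver (60 ± 10 HU of voxel
texture) on a −100 HU background with 0–3 hypodense ellipsoidal tumors
(20 ± 10 HU) and 5 HU global Gaussian noise. Tumor centers are proposed
inside a shrunken liver and then verified voxel-exactly against the
liver's analytic quadratic field, with rejection and retry (error after
200 failed proposals). Labels derive from the same geometry, so ground
truth is exact by construction.

What this preserves from real CT: the HU scale and a meaningful windowing
step (background clips to the lower bound, liver and lesions fall inside
the window), low lesion/parenchyma contrast (40 HU separation, ~14 HU of
combined noise), extreme class imbalance (tumors are a few hundred voxels
of ~110k), lesions strictly inside liver, and a volumetric structure that
makes the 2.5D stacking non-trivial. What it does not preserve: organ
shape complexity (real livers are not ellipsoids), neighboring organs of
similar intensity (no spleen/heart/stomach confusers), partial-volume
boundary effects, anisotropic spacing, and acquisition artifacts. The
phantom task is therefore much easier than LiTS-style segmentation — the
desk-scale tumor Dice of ~92% says the pipeline learns; it says nothing
about clinical performance.

## Numerical choices

* **Autodiff engine.** All layers build on a small NumPy reverse-mode
  engine (`hepaseg.autograd`): tensors record parents and a backward
  closure; `backward()` runs an iterative topological sort. Training
  arithmetic is float32; the oracle tests run the same code in float64.
* **Convolution.** `conv2d` is im2col + one GEMM. The input gradient is
  computed as a correlation of the output gradient with the spatially
  flipped, channel-transposed kernel at padding `d·(k−1) − p`, again as
  im2col + GEMM — the same cost as the forward pass, instead of a
  scatter-add over taps. Gradients of every conv variant are verified
  against central differences in the test suite.
* **Batch norm** is a single fused op with the closed-form backward
  `gx = γ·inv·(g − mean(g) − x̂·mean(g·x̂))`, avoiding a six-node graph
  per BN call; running statistics use momentum 0.1. In eval mode BN
  collapses to a precomputed scale-and-shift.
* **Scalar promotion.** Python scalars are folded into the array dtype at
  op construction; without this NumPy's promotion rules silently upcast
  the whole float32 graph to float64 (measured 4× slower).
* **MSFE pooling branch without BN.** Batch statistics of a 1×1 spatial
  map are degenerate for small batches (variance across ≤4 values), so
  the pooling branch uses conv + ReLU only; the reweighting path, which
  the additive skip stabilizes, keeps conv-BN-ReLU.
* **Zero-initialized gates.** Both the HGA gate and its convexity
  contract, and the global-context reweighting (`a = σ(…) ∈ (0,1)`,
  output `x(1 + a)`), start from neutral blends, which keeps early
  training close to the plain U-Net signal path.
* **Determinism.** All randomness flows from integer seeds through
  `numpy.random.default_rng`; per-volume child seeds are derived as
  `default_rng([master, index])`, so any volume can be regenerated
  independently and dataset contents are independent of how many volumes
  are requested. On a single-threaded BLAS the whole pipeline is
  bit-reproducible.

## Limitations

* The phantom task is far easier than clinical segmentation; reported
  Dice values are pipeline-health indicators, not clinical claims.
* The reference profile (480×480, base width 64, 120 epochs) is
  documented but computationally out of reach of this CPU-only
  implementation; only the desk profile is exercised.
* The engine supports exactly the layer set the network needs (stride-1
  'same' convs, 2×2 pooling/upsampling); it is not a general framework.
* MSFE's dilation rates (4/8/12) exceed the 6×6 bottleneck of 96×96 desk
  inputs, so the dilated branches are mostly zero-padding in that regime
  (a warning is emitted); they become meaningful at reference resolution
  (30×30 bottleneck).
* Bit-reproducibility holds for a fixed platform/BLAS; across different
  BLAS builds results match only to floating-point tolerance.
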