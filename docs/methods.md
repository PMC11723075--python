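# Methods

## Problem and model

`osteoformer` segments bone from single-channel CT-slice-like images with a
hierarchical transformer encoder-decoder tuned for *small* training sets.
The encoder is a SegFormer-style mix transformer: four sequential stages,
each an overlapped patch embedding (strided convolution plus token layer
norm) followed by transformer blocks pairing spatially-reduced multi-head
self-attention with a Mix-FFN. Two modifications target data efficiency:

1. **Deeper Mix-FFN convolution stack.** The Mix-FFN expands tokens with a
   linear layer, applies M consecutive 3x3 depthwise convolutions with GELU
   between them at the expanded width, and projects back. M = 1 is the
   standard Mix-FFN; the data-efficient configurations use M in 2..5
   (ablation grid `mixffn_depth_grid`). Larger M widens the receptive
   field of the positional pathway without attention cost.
2. **Raised resolution schedule.** Stage resolutions are fractions of the
   input side. The baseline schedule is (1/4, 1/8, 1/16, 1/32) — 64/32/16/8
   px at a 256 px input; the data-efficient schedule is (1, 1/2, 1/4, 1/8),
   keeping the first stage at full input resolution. Fractions above 1
   bilinearly upsample before embedding (the 512 px ablation row); this is
   off by default.

Attention cost at full resolution is held down by spatial reduction: keys
and values come from the token grid downsampled r-fold by a learned r x r
strided convolution (per-stage ratios default to 8, 4, 2, 1).

Two decoders map the four-level feature pyramid to per-pixel logits:

* **All-MLP** (baseline): per-level linear projection to a shared width,
  bilinear upsampling to the finest level, concatenation, linear fusion,
  class projection, upsample to the image grid.
* **FPN with attention** (proposed): top-down pathway — the coarsest level
  passes a 3x3 convolution and a residual pre-norm spatially-reduced
  self-attention block; each finer level adds its 3x3-convolved 1x1-lateral
  projection to the upsampled running map, then attends again. "Combine" is
  element-wise addition at a shared decoder width (128; 32 in the tiny
  presets), the standard FPN fusion. Disabling `decoder_attention` removes
  every attention block but keeps conv/fusion (the "without attention"
  ablation row). The class projection is followed by the final bilinear
  upsample, keeping both decoders comparable.

The four preset systems (`baseline`, `data_efficient`, `fpn`, `proposed`)
are the cross product of {baseline, raised} encoder schedule and {allmlp,
fpn} decoder, matching the compared systems in the ablation studies. No
class token is used anywhere: dense prediction needs none.

## Training protocol

Pixel-wise unweighted cross-entropy over {background, foreground}, Adam at
learning rate 1e-3, batch size 4, 20 epochs. No schedule, weight decay,
early stopping or class weighting. Validation IoU is logged per epoch but
never used for selection (the protocol is fixed-epoch). Binarisation is
per-pixel argmax (probability 0.5 for two classes). A single integer seed
drives weight initialisation (truncated normal, std 0.02, for projections;
fan-out-scaled normal for convolutions; the class head uses std 0.02 so
initial logits start near zero) and batch shuffling; `deterministic=True`
makes training bit-reproducible on one machine.

The tensor backend is an in-repo numpy reverse-mode autodiff engine
(`osteoformer.nn`) providing exactly the operations these models need;
every differentiable op is validated against central finite differences,
and convolution values against `scipy.signal.correlate2d`. Convolutions are
computed tap-by-tap (fused multiply-adds for depthwise, one GEMM per kernel
tap for dense), avoiding the k^2-fold im2col memory blow-up.

## Metrics

IoU = TP/(TP+FP+FN), DSC = 2TP/(2TP+FP+FN) from per-image pixel confusion
counts of the foreground class. Per image the identity DSC = 2 IoU/(1+IoU)
holds exactly, which is why Dice reads above IoU on the same prediction.
Both-empty masks score 1 (correct prediction of absence). Set aggregation
is the arithmetic mean of per-image scores, matching per-image IoU
reporting; pooled-count aggregation is available behind `pooled=True`.

## Model comparison statistics

K-fold cross-validation produces a folds x methods mean-IoU matrix. The
Friedman test ranks methods within each fold (average ranks on ties, the
standard tie-corrected denominator; fully tied matrices return statistic 0,
p 1) and refers the statistic to chi-square with k-1 df. With identical
tie-free per-fold orderings the statistic attains its maximum N(k-1): 40.00
for 10 folds x 5 methods, 8.00 for the 2-fold swap design, which the test
suite reproduces analytically. When Friedman is significant at alpha =
0.05, the Nemenyi post-hoc compares each pair's mean-rank difference
against the studentized range with infinite error degrees of freedom
(q = diff / sqrt(k(k+1)/(12N))). The 2-fold "swap" design used for the
train/test-exchanged dataset is expressed as ordinary 2-fold CV.

## Synthetic phantoms

Phantoms make every stage testable without patient data. Three families
emulate the geometric regimes of the target anatomies: `vertebra` (body
ellipse plus posterior arch with a cut-out foramen and processes — one
markedly concave component, solidity < 0.95), `hand` (per-finger phalanx
capsules and carpal blobs with >= 1 px background gaps — at least five
components), `femur` (a flared shaft capsule — one roughly convex
component). Masks are the exact analytic support of the shapes; images get
distance-shaded bone intensity (~0.62-0.90) over dim textured background
(~0.12), clipped to [0, 1]. Generation is a pure function of
(anatomy, size, seed). Sizes must be divisible by 32 (four halvings plus
patch stride).

What the phantoms do **not** emulate: CT physics (Hounsfield calibration,
beam hardening, partial-volume effects), 3-D context, anatomical variation
beyond jittered shape parameters, or annotation noise in real ground
truths. Passing phantom tests therefore demonstrates that the
architecture, optimisation and statistics machinery behave as specified —
not that clinical accuracy figures transfer.

Augmentation adds zero-mean Gaussian intensity noise. The noise sigma is
configurable, default 0.05 on the [0, 1] scale — visible but
non-destructive. "Augmented to three times" is defined as the original
plus two noisy copies (276 -> 828). Splitting is train:test:val = 8:1:1,
test/val counts rounded half-up, remainder to train (276 -> 220/28/28).
The default pipeline splits first and augments the training set only
(leakage-free); `augment_before_split=True` reproduces the
augment-then-split ordering.

## Desk-scale study conditions

All learning checks run on one CPU with the `tiny_*` presets (channels
16/32/64/128, one block per stage, decoder width 32) — chosen as the
smallest configuration that still exercises every architectural component:

* **Overfit check:** one 64 px vertebra phantom, batch 1, 200 Adam steps;
  the proposed tiny model must reach IoU > 0.9 on its own training image
  (it reaches 1.0 for seeds 0-2).
* **Held-out comparison:** 24 mixed-anatomy training phantoms, 30 held-out,
  64 px, the full 20-epoch protocol, three seeds; the proposed
  configuration must match or beat the baseline configuration's mean IoU.
  The raised resolution schedule is decisive here: the baseline's coarsest
  pyramid (16 px first stage at 64 px input) cannot represent thin
  structures such as inter-phalanx gaps.
* **Concordant score matrix:** fold-level IoUs drawn around the published
  10-fold per-method means with their published standard deviations,
  clipped so no fold reverses the method ordering (the smallest
  inter-method gap, 2.2 IoU points, dwarfs the spreads). This realises the
  fold concordance implied by the Friedman statistic attaining its
  maximum.

## Numerical and design choices

* Bilinear resampling uses the half-pixel convention everywhere.
* Attention softmax is max-subtracted; row-stochasticity is property-tested.
* Overlapped embeddings: stride 4 uses a 7x7 kernel (baseline stage 1),
  strides 1-2 use 3x3, all padded to preserve the schedule arithmetic.
* Mix-FFN expansion ratio defaults to 4; the added depthwise layers stack
  residual-free with GELU between, reducing exactly to the baseline
  topology at M = 1.
* A shared M across stages is the default reading of the depth ablation;
  per-stage depth is expressible by constructing stages directly but is not
  a preset.
* Checkpoints are `.npz` archives of named weights with an embedded JSON
  copy of the architecture config.
* Spatial-reduction ratios in the FPN decoder mirror the encoder's
  per-level ratios, making decoder attention affordable at full resolution.

## Known limitations

* The engine is single-threaded numpy (plus BLAS); training the full-width
  presets (e.g. MiT-B3-like `proposed`) at 256 px is out of desk-scale
  reach. The tiny presets are the supported test scale.
* Spatial-reduction ratios must not exceed the corresponding feature-map
  side; the tiny presets respect this for inputs >= 32 px (proposed) /
  >= 64 px (baseline with the FPN decoder).
* PNG round-trips quantise intensities to 8 bits; masks survive exactly.
* U-Net, DeepLabV3+ and Mask2Former are not reimplemented; the statistics
  harness accepts their fold scores as input (`ScoreMatrix.from_csv` or
  trainer callables in `run_cross_validation`).
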