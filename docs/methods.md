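# Methods

This note records the scientific and numerical choices behind the package,
in the order the pipeline runs.

## HOG pseudo-labels

The auxiliary target for an image is a classic HOG descriptor:

1. resize to W×H = 64×128 (width × height, the pedestrian-window
   convention) with bilinear interpolation;
2. grayscale by luminance (0.299 R + 0.587 G + 0.114 B);
3. central differences gx(r,c) = I(r,c+1) − I(r,c−1) and the analogous gy
   (correlation with [−1, 0, 1]); borders replicate-padded; magnitude
   √(gx²+gy²); unsigned orientation atan2(gy, gx) folded into [0°, 180°),
   defined as 0 where the magnitude is 0;
4. the window is partitioned into non-overlapping w×h cells (defaults
   16×16; trailing partial cells dropped, giving ⌊W/w⌋×⌊H/h⌋ cells); each
   pixel votes its full magnitude into the single bin whose half-open
   interval [i·180/k, (i+1)·180/k) contains its orientation — **no
   bilinear vote splitting**, a deliberate simplification relative to the
   Dalal–Triggs original;
5. 2×2-cell blocks slid at 1-cell stride are flattened row-major and
   L2-normalized as v/√(‖v‖² + ε²) with ε = 1e-5 (plain L2, no clipping),
   then concatenated row-major.

The length is (⌊W/w⌋−b+1)·(⌊H/h⌋−b+1)·b²·k for b-cell blocks; with the
defaults this gives 504, and 864 / 2520 for 12×12 / 8×8 cells. Plain
concatenation of the per-cell histograms (b = 1) is available but does
*not* reproduce those dimensions — a 16×16-cell tiling of 64×128 would give
only 4·8·6 = 192 components — which is why overlapping normalized blocks
are the package's default reading of the descriptor.

Properties the tests enforce: vote conservation (cell votes sum to the
total magnitude over covered pixels), photometric invariance of nonzero
normalized blocks under intensity scaling, entries in [0, 1+ε], bit-exact
determinism, and agreement with an independent per-pixel double-loop
reference to 1e-10.

Open choice, fixed once: gradients are computed on the luminance image, not
per color channel with max-magnitude selection.

## Networks

Both backbones and the autograd engine they run on (`hogseg.nn`) are part
of the package: a reverse-mode tape over numpy arrays with convolution
(stride 1, evaluated as one GEMM per kernel offset in NHWC layout), ReLU,
2×2 max-pooling (floor mode in the backbones; ceil mode in the heads),
nearest-neighbour upsampling, channel concatenation, and linear maps.
float32 is the working dtype; the gradient-check tests switch the engine to
float64. All initialization is He-style, drawn from an RNG keyed by
(seed, layer path), so a layer's weights are independent of which other
layers exist — attaching or removing auxiliary heads provably leaves the
backbone's initialization untouched, and the β = 0 training trajectory is
bit-identical to the single-task network's.

* **UNet** — `n_stages` resolution levels (default 5, desk scale 3),
  double-conv blocks, nearest-upsample + conv decoders with skip
  concatenation, 1×1 output conv. One auxiliary head on the bottleneck.
* **U2Net** — residual U-blocks (a 2-level mini-UNet whose output adds to a
  projected input) at every stage; side outputs (3×3 conv per stage,
  resized to input resolution) fused by a 1×1 conv; cross-entropy averages
  over the fused map and all side maps (deep supervision). One auxiliary
  head on the bottom stage and on each decoder stage, i.e. `n_stages`
  heads. Which decoder tensor feeds each head is an open choice; the
  package uses each stage's output feature map before its side conv.
* **Auxiliary head** — 1×1 adapter conv to 3 channels (decoder features are
  many-channel and rectangular, so the canonical (3, h, h) head input needs
  an adapter), two (3-channel 3×3 conv, padding 1 → ReLU → 2×2 ceil-mode
  max-pool) stages, a nearest resize to the head's reference pooled size
  (identity at the build-time input size; it makes the output length
  input-size-independent), flatten (3·⌈s/4⌉·⌈s'/4⌉), linear to D with
  zero-initialized bias.

Input spatial sizes must be divisible by the backbone's downsampling factor
(2^(n_stages−1) for UNet; 2^n_stages for U2Net because of the in-block
pool). Heads require their reference feature map to be at least 4×4.

## Training

Joint loss α·CE + β·MSE with α = β = 1 by default; the dataset-mean 1/N is
realized as the mini-batch mean. CE reduces by mean over pixels (no class
weighting); the multi-head HOG loss is the unweighted mean over heads. When
β = 0 the auxiliary branch is skipped entirely. Optimization is Adam
(framework-default moments, no weight decay) with lr₀ = 2e-4 halved every
50k iterations, a 150k-iteration budget and validation every 1k — the
full-scale schedule, which desk-scale configurations override only in the
iteration budget. The best-by-validation-mIoU parameter set is
checkpointed (npz with the specs embedded); the selection rule is this
package's choice since best-vs-final is otherwise unspecified. Batch size
is fully configurable (default 4). Non-finite loss aborts training and
keeps the last good checkpoint. No augmentation by default; if a user adds
any, pseudo-labels must be recomputed from the augmented image.

The sweep harness trains one run per (α, β) × HOG-dimension cell on an
identical split (audited by a dataset hash) and emits the ablation-style
table plus a dimension-vs-mIoU curve. The shipped weight grid is
(0.01,1), (0.1,1), (1,1), (1,0.1), (1,0.01).

## Evaluation

IoU_c = TP_c/(TP_c+FP_c+FN_c); mIoU averages over *evaluated* classes:
a class absent from both masks contributes nothing rather than 0 or 1.
Pooled-confusion averaging is the default; per-image averaging feeds
distribution plots. Both are provided because challenge protocols differ.
No ignore label by default (configurable). Predictions are argmaxed at the
model's resolution and nearest-resized to the mask if needed. The
varying-training-size protocol uses nested subsets (one permutation,
prefixes per fraction) so curves across fractions are comparable.

## Synthetic scenes

The generator emulates only the structural premise that makes HOG useful
for this problem: smooth, low-gradient multi-class anatomy (soft-edged
ellipses over a gently shaded background, Gaussian intensity noise with
σ = 2 intensity units, clipped) versus elongated, straight-edged,
high-gradient instruments (rotated capsules, hard edges, no
anti-aliasing). The default class plan is background + 4 anatomy + 1
instrument = 6 classes at 64×128, mirroring the coarse-task structure of
cataract-surgery benchmarks at small scale. Scenes are deterministic in
(seed, index); splits take disjoint index ranges.

What the generator does **not** emulate: real tissue texture, specular
highlights, motion blur, occlusion chains, video correlation, or the pixel
statistics of any real benchmark. Tests passing on these scenes show the
pipeline is implemented correctly and that the auxiliary signal behaves as
designed (boundary cells carry more HOG energy than anatomy interiors);
they do not certify performance on real surgical data.

## Problem sizes and defaults used in tests

Desk-scale profile: 64×128 inputs, UNet width_scale 0.125 (8 base
channels), 3 stages, batch 2. The overfit check trains 4 scenes for 800
iterations (final joint loss < 10 % of initial; ~1 % is typical by 1200).
The single- vs multi-task comparison trains 5 seeds per variant for 150
iterations on 6 scenes and reports median held-out mIoU; at this scale the
direction of the gap varies with seed, so it is logged rather than
asserted. These sizes are the package's reproducible defaults for
continuous testing, chosen so the whole suite runs in minutes on one CPU.

## Known limitations

* Stride-1, padding-0/1 convolutions only; no dilation, batch norm or
  dropout — the backbones are faithful in topology, not in every layer
  detail of GPU-scale implementations.
* The full-scale 6-stage U2Net needs inputs ≥ 256 pixels per side for its
  deepest head; desk-scale configurations use 3–4 stages.
* Single device, single thread; no mixed precision or distribution.
* The descriptor is the unsigned-orientation variant only; no multi-scale
  pyramids and no signed 0–360° bins.
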