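# Methods

## The balanced pyramid

A feature pyramid is an ordered list of `C × H_l × W_l` maps whose spatial
shapes halve (ceil) per level. The balanced feature pyramid treats the
levels symmetrically: every level is rescaled to the resolution of one
intermediate level, the rescaled maps are averaged into the balanced
semantic map `C̄ = (1/N) Σ C_r`, the map is refined, and the refined map is
rescaled back and added onto every level. The averaging stage has no
learned parameters; the only trainable pieces are in the refinement.

Rescaling conventions:

- **Downscaling** uses non-overlapping max pooling with kernel = stride =
  the integer scale factor. A two-octave jump pools a single 4×4 window,
  which equals two repeated 2×2 max pools exactly.
- **Upscaling** uses nearest-neighbour interpolation with the pixel-centre
  convention `src = floor((i + 0.5)·H_in/H_out)`; bilinear is available as
  a config option on the FPN path. Nearest is the default because it makes
  constant maps survive every rescale exactly, which in turn makes the
  algebraic identity tests exact rather than approximate.
- **Non-integer factors** (odd sizes produced by ceil-halving, e.g. 5×5 to
  3×3) fall back to nearest-neighbour sampling to the exact target shape in
  either direction rather than failing.
- The intermediate level defaults to index `N // 2` — for a four-level
  pyramid, the coarser of the two middle levels — and is configurable.

All pyramid arithmetic is float32; oracle comparisons in the tests use
1e-6 absolute tolerance, which float32 rescale-average round-off meets with
roughly a factor-3 margin at the tested sizes.

## Attention refinement

The channel gate pools the map globally by average and by max, pushes both
descriptors through one shared two-layer MLP (`C → C/r → C`, ReLU between
the layers), sums the branch outputs, and applies a sigmoid. The spatial
gate stacks the per-pixel channel average and channel max into a 2-plane
image, convolves with a single 7×7 kernel (zero padding 3, so H×W is
preserved), and applies a sigmoid. The refinement gates the balanced map
with both in parallel and sums:

    F_ab = Mc ⊗ F_b ⊕ Ms ⊗ F_b .

Design choices where the design was genuinely open:

- **ReLU placement.** The shared MLP applies ReLU between W₀ and W₁, the
  standard design of channel-attention blocks of this family.
- **Reduction ratio.** Default r = 16, clamped (by decrementing to the
  nearest divisor of C) so the bottleneck keeps at least one unit; r must
  divide C and parameter construction rejects other combinations.
- **Parallel, not sequential.** The two gated copies are summed, so with
  inputs bounded by B the output is bounded by 2B (each gate is strictly
  inside (0,1)). No normalisation follows the sum; the up-to-2× magnitude
  is intentional and asserted in the tests, and the downstream addition in
  the strengthen stage tolerates it.
- **Biases** in the MLP and the 7×7 conv are included by default and can be
  switched off in the neck config.
- **Plane order** in the spatial gate is [average; max].
- **Initialisation**: Kaiming-uniform weights, zero biases, seeded.

With all gate parameters zero, both gates are exactly 0.5 everywhere and
the refinement reduces to the identity (0.5F + 0.5F = F) — the anchor of
the exact identity tests.

## Necks

`fpn_forward` is the standard top-down FPN: 1×1 lateral convolutions to a
uniform width, nearest-neighbour top-down addition, 3×3 output smoothing.
`abfp_forward` applies integrate → refine → strengthen to any
uniform-channel pyramid and preserves its shape signature, which is the
contract that makes it stackable on FPN outputs (the configuration used
here) or on any other fusion strategy. ABFP operates on FPN outputs rather
than raw backbone features because the unweighted balanced mean requires
equal channel counts, which only the neck outputs have. With attention
off, the refinement is replaced by a single 3×3 convolution — the ablation
arm that isolates the value of the gates. The extra parameter cost of the
refinement has a closed form (`2·C·C/r` MLP weights + `7·7·2` kernel taps,
plus biases) asserted against the counted parameters.

## Evaluation protocol

Single foreground class. Detections are pooled over images, sorted by
descending score (ties broken by input order, stable), and greedily matched
— each detection to the highest-IoU unmatched ground truth of its image at
the given threshold, each ground truth usable once. AP is the 101-point
interpolated area under the precision envelope (recall grid 0:0.01:1,
unreachable recalls contribute zero). Headline AP and AR average the ten
IoU thresholds 0.50:0.05:0.95; AP50/AP75 fix the threshold. AR uses a cap
of 100 detections per image (configurable). Images with no ground truth
contribute false positives only; a dataset with no ground truth at all has
undefined recall and AP is defined as 0.

## Synthetic scenes

Each scene is a smooth Gaussian random field (σ = 8 px, amplitude 0.08
around grey level 0.45) plus `n_lesions` ellipses with uniformly random
semi-axes (6–16 px at 128×128), orientation, and position fully inside the
image. Lesion interiors sit `contrast = 0.15` above the local background —
deliberately low — with edges blurred by a σ = 1 px Gaussian and additive
pixel noise σ = 0.02. Boxes are tight to the ellipse mask extents.
Generation is a pure function of the seed.

What the generator does *not* model: Hounsfield calibration, anatomy and
confusable neighbouring organs, multi-phase contrast enhancement,
inter-slice 3-d structure, scanner artefacts, annotation noise. Passing
the end-to-end tests therefore demonstrates that the pipeline is wired
correctly and can learn low-contrast blobs — not clinical performance on
real CT.

## Micro detector

A four-stage convolutional backbone (3×3 stride-2 convs; widths 16/32/64/128
at strides 4/8/16/32) feeds the FPN (width 32) and optionally ABFP, then a
shared head (3×3 conv + ReLU, parallel 3×3 classification and regression
convs). Anchors: one size per level (4× the stride) at aspect ratios
{0.5, 1, 2}; assignment positive at IoU ≥ 0.5, negative below 0.4, ignored
between, with every ground truth claiming its best anchor. Losses follow
the single-stage convention: focal loss (γ = 2, α = 0.25, classification
bias initialised to a 0.01 foreground prior) plus smooth-L1 on standard
box-delta encodings, both normalised by the positive count.

Training is SGD with momentum 0.9, weight decay 1e-4, initial learning
rate 0.01, linear warmup (factor 1/3 over 50 iterations), batch 4, 50%
horizontal flips, and global gradient-norm clipping at 10 — without
clipping, an occasional large early gradient (a batch dominated by
hard-negative anchors before the warmup completes) can destabilise the
randomly initialised micro network. The desk-scale schedule is 12 epochs with 10× drops at
epochs 8 and 11, mirroring the full-scale 24-epoch/[16, 22] recipe at half
length. The deep pretrained backbone of the full-scale setting is replaced
by random initialisation; the micro backbone exists to exercise the neck,
which is backbone-agnostic, not to reach clinical accuracy. The loop is
single-process numpy, so a fixed seed reproduces the loss curve
bit-identically.

The study conditions for the end-to-end check are 200 images at 128×128
with 2 lesions each, an 80/20 train/validation split by image index, and
the 12-epoch schedule — about 45 s of training on one CPU core. Inference
thresholds scores at 0.05, applies greedy NMS at IoU 0.5, and keeps at most
100 boxes per image.

## Autodiff engine

Training runs on a small reverse-mode automatic-differentiation engine
(`abfp.autodiff`): a float32 tensor wrapping numpy arrays with
broadcasting arithmetic, matmul, fused im2col convolution, reductions,
nearest-neighbour gather/scatter, and the pointwise nonlinearities the
losses need. `amax` routes gradient to all elements attaining the maximum;
ties have measure zero for the random inputs used in gradient checks.
Gradient correctness is established two ways: per-primitive finite
differences, and an end-to-end check of the refinement against central
differences through an independent float64 scalar oracle (agreement well
below 1e-4 relative).

## Numerical and degenerate-input conventions

- Zero-sized maps, non-halving pyramids, mismatched channel counts,
  degenerate (zero-area) boxes, empty datasets, and out-of-range configs
  are rejected with explicit messages.
- A single-level pyramid integrates to itself; equal-shape rescales are
  identities in either mode.
- Detection score ties break by input order (stable sorts throughout).
- Non-finite training loss aborts with a diagnostic rather than continuing.

## Known limitations

- CPU-scale only; the engine is vectorised but unbatched convolutions of
  large widths are not competitive with GPU frameworks.
- 2-d slices only; no 3-d context across slices.
- Single foreground class; no per-size AP breakdown.
- The sequential-attention and deformable-convolution comparison arms, and
  alternative fusion strategies (PAFPN/BiFPN), are out of scope — the neck
  interface accepts any uniform-channel pyramid producer, so they can be
  plugged in externally.
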