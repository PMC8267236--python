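# Methods

## The segmentation problem

Gliomas are graded on multi-modal MRI into nested tissue compartments:
peritumoral edema (label 2), GD-enhancing tumor (label 4) and the
necrotic / non-enhancing core (label 1), on a background of normal brain
(label 0).  Evaluation follows the standard nested-region convention:

* **WT** (whole tumor) = labels {1, 2, 4}
* **CT** (core tumor) = labels {1, 4}
* **ET** (enhancing tumor) = label {4}

so ET ⊆ CT ⊆ WT always holds for targets derived from a label map.  The
network predicts the three region channels independently (per-channel
sigmoid, threshold 0.5); an optional post-composition step re-imposes
nesting on predictions by intersection.  The two textual conventions in
circulation (ET = label 4 vs ET = label 1) differ only in the
`REGION_LABELS` constant in `aanet.brats_io`, one edit away.

## Architecture

The network is a four-stage U-Net-shaped encoder-decoder over 4-channel
(T1, T2, T1ce, FLAIR) axial slices whose spatial size must be divisible by
16.  Stage widths double per stage from `base_channels` (default 32; the
test and acceptance runs use a reduced width of 8).  The bottleneck width
is twice the deepest stage.

**EDS (enhanced down-sampling) stage.**
`h = maxpool₂( convBNReLU₃ₓ₃(convBNReLU₃ₓ₃(x)) + convBNReLU₁ₓ₁(x) )` — a
residual double convolution; the residual projection uses a 1×1 kernel so
it is addable to the double-conv output (the kernel size of that branch is
a design choice here).  The side feature
`a = concat( convBNReLU₁ₓ₁(G¹) , convBNReLU₁ₓ₁(G²) )` fuses the low-level
activation G¹ (after the first 3×3 conv) with the high-level G² (after the
second), each projected to half the stage width so `a` returns to the
stage's C×H×W.  `a` feeds both the skip connection and a deep-supervision
head; `h` feeds the next stage.

**MSC (multi-scale connection).**  Replaces the plain skip: four parallel
branches over `a` — a 1×1 conv and three 3×3 dilated convs with
(padding, dilation) = (6,6), (12,12), (18,18), preserving spatial size —
concatenated along channels and fused back to the stage width by a
1×1 conv-BN-ReLU.  The fusion kernel size is not dictated by the design;
1×1 was chosen as the cheapest channel-mixing fusion.  Each of the four
skip positions can be switched to a plain skip (`msc_positions`),
reproducing the position-ablation configurations.

**DAF (dual-attention fusion) bottleneck.**  Two 3×3 conv-BN-ReLU layers
produce the trunk `y`, followed by two attention heads:

* *Positional attention*: 1×1 projections A, B (channels reduced to C/8)
  and C (full width) of `y`, reshaped to matrices over the N = H·W pixel
  positions.  The affinity `s_ji = softmax_i(A_i · B_j)` row-normalizes
  over source positions i; the output is `EA_j = α Σᵢ s_ji C_i + y_j` with
  a learnable scalar α.
* *Channel attention*: affinities are taken directly between the raw
  channel vectors of `y` — no convolutions, so the head is exactly
  equivariant under channel permutation — with
  `m_ji = softmax_i(x_j · x_i)` and `CA_j = β Σᵢ m_ji x_i + y_j`.

Both scales α, β initialize to 0, making each head an exact identity at
step 0; attention influence is learned, never imposed.  The softmax is
computed with the standard max-subtraction, which changes nothing
mathematically.  Fusion variants: DAF1 (default)
`conv₁ₓ₁(EA + CA)`; DAF2 adds a parallel 1×1 side branch y′ of the input
and fuses `concat(EA + y′, CA + y′)`; DAF3 combines both paths,
`concat(EA + CA, EA + y′, CA + y′)`.  DAF2/DAF3 wiring beyond this is a
documented best-effort interpretation; DAF1 is the fully pinned default.
A supervision head on the fused feature drives the bottleneck loss term.

**US (up-sampling) stage.**  The deeper feature is upsampled 2× by
bilinear interpolation followed by a 1×1 conv, concatenated with the skip
feature at that level, and passed through the same residual double-conv
structure as EDS (pooling removed).  Upsampling *precedes* concatenation:
with four skip levels at 1×, ½, ¼ and ⅛ resolution and the bottleneck at
1/16, exactly four 2× steps restore the input resolution — this is the
only wiring in which all four skip levels are consumed and the final head
emits full-resolution logits.  Each US stage carries a deep-supervision
head; the final 1×1 head maps the last decoder feature to the three region
logits.

Every supervision head is a 1×1 projection to 3 channels bilinearly
upsampled to the input resolution, so one loss routine serves all heads
(4 EDS + 4 US + 1 DAF + 1 final = 10 maps).

## Loss

Per head, with prediction probabilities p = sigmoid(logits):

* `L_BCE = −mean( y·log p + (1−y)·log(1−p) )`, probabilities clamped to
  [1e-7, 1−1e-7];
* `L_Dice = 1 − 2·Σ T·P / (Σ T² + Σ P² + ε)`, ε = 1e-5, computed per
  (sample, region-channel) over the spatial dims and averaged.  The
  squared-sum similarity is maximized at perfect overlap, so the loss is
  one minus it — the only orientation a minimizer can use;
* per-head loss `L = α·L_BCE + L_Dice`, α = 0.5.

The network total is
`L_total = λ₁(L_down + L_up) + λ₂·L_dual + L_result` with λ₁ = 0.4 and
λ₂ = 0.2, where `L_down`/`L_up` are *means* over their four heads (so the
λ weights are invariant to head count, a choice made here) and `L_dual`/
`L_result` are the bottleneck and final heads.  Loss terms are accumulated
in float64 on top of the float32 network so the decomposition identity
holds to ~1e-7.

## Preprocessing

Per case: (1) z-score each modality volume over its nonzero (brain)
support — background voxels would otherwise dominate the statistics — with
background kept exactly 0; (2) center-crop the 240×240 in-plane frame to
160×160 (offsets (40, 40)); (3) slice along Z into 155 axial planes;
(4) stack the four modality planes per slice in the fixed order T1, T2,
T1ce, FLAIR.  Normalization precedes cropping.  All 155 slices are kept,
including tumor-free ones; train/validation splitting is case-level to
avoid leakage between slices of one patient.

## Metrics

Dice `2TP/(2TP+FP+FN)`, precision `TP/(TP+FP)`, sensitivity `TP/(TP+FN)`
and the plain (not 95th-percentile) symmetric Hausdorff distance between
mask boundaries, in pixel units, per slice, averaged over the dataset per
region.  Boundary = foreground pixel with ≥ 1 background 4-neighbor.
Conventions for degenerate slices: both masks empty → perfect scores
(Dice/precision/sensitivity 1, Hausdorff 0); exactly one empty → overlap
indexes fall out of the formulas, Hausdorff returns a sentinel (default:
the image diagonal).  Published Hausdorff magnitudes on this task (~1–2)
imply a normalization that is not described anywhere we could follow;
pixel units are reported and no attempt is made to match that scale.

## The phantom generator

Real BraTS data cannot be redistributed, so every pipeline stage is
exercised on synthetic phantoms: a circular "brain" (radius 0.45 of the
image) on a zero background, with three concentric ellipses — edema ⊃
enhancing ⊃ necrotic, default semi-axes 0.30/0.18/0.08 of the image size —
labeled 2/4/1.  Four intensity channels are per-tissue constant lookups
plus i.i.d. Gaussian noise (σ = 0.05 on a [0,1] intensity scale);
the contrast table makes FLAIR brightest on edema and T1ce on enhancing
tumor, mimicking the clinical pattern.  Dataset generation jitters tumor
position, overall scale (×0.85–1.1) and ellipse axis ratio per slice,
all driven by one seed; output is bit-reproducible.  A 3-D writer emits a
BraTS-layout case (NIfTI quartet + segmentation) in which the tumor's
in-plane radius shrinks away from the central slice like a ball.

What the phantoms do *not* model: tumor shape irregularity, texture,
Rician noise, bias fields, partial-volume effects, inter-modality
misregistration.  Tests passing on phantoms therefore demonstrate the
correctness of the computation — shapes, losses, metrics, optimization —
not clinical-grade segmentation accuracy on real MRI.

## Training

Adam (lr 3e-4, β = (0.9, 0.999)), batch size 16, up to 100 epochs, early
stopping with patience 20 on the mean validation Dice across WT/CT/ET
(checkpoint = best monitored value).  "Validation accuracy" is not pinned
more precisely by the training recipe this follows; mean validation Dice
is the monitor chosen here.  No data augmentation.  A `(config, seed)`
pair fixes initialization (He-normal) and data order exactly.

## Numerical engine

No deep-learning framework is used: the package runs on its own compact
NumPy reverse-mode autodiff engine (`aanet.nn`) — broadcasting arithmetic,
batched matmul, im2col convolution (stride 1, arbitrary dilation), fused
batch normalization, 2×2 max pooling, bilinear resizing, softmax, and
Adam.  Every analytic gradient is validated against central finite
differences in the test suite, and convolution values are cross-checked
against `scipy.signal.correlate2d`.  The working dtype is float32; loss
reductions are cast to float64.

## Problem sizes used in verification

The verification suite and `scripts/acceptance.py` run on 1 CPU:
attention properties on 1,000 random 8×4×4 inputs and brute-force oracle
checks up to 8×6×6; the preprocessing contract on one full synthetic
240×240×155 case; region nesting on 10,000 random label maps; and a
memorization ("overfit") run — a base-8-channel network trained on eight
160×160 phantom slices with full-batch Adam at lr 3e-4 for at most 200
steps, stopping once mean training Dice exceeds 0.95.  At the suite's
fixed seed it passes Dice 0.95 within ~90 steps; the checked bound is
> 0.90.  Like any short stochastic optimization the step count at which
the bound is crossed varies with the seed, which is why the suite pins one.
Benchmark-scale training on the real corpus (tens of thousands of slices,
GPU-scale compute) is out of scope.

## Known limitations

* 2-D slice-wise segmentation only; no 3-D context between slices.
* DAF2/DAF3 are interpretations; only DAF1 is fully specified.
* The decoder upsampling operator is bilinear + 1×1 conv; transposed
  convolution is not implemented.
* Hausdorff is exact but O(boundary²) per slice in the worst case via
  `scipy.spatial.distance.directed_hausdorff` (early-breaking in practice).
* The engine is single-threaded NumPy; wall-clock cost, not correctness,
  limits feasible model sizes.
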