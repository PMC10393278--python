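# Methods

## Problem and approach

`splintleaf` measures the one-sided area of a single leaf from a calibrated
RGB photograph. The acquisition assumption is the *splint* protocol: the leaf
is clamped flat between transparent plates parallel to the camera plane, so
its imaged silhouette equals its true outline. A calibration square of known
physical area S_c (5 mm x 5 mm by default) sits in the frame; once a
segmentation network has produced a leaf mask, the physical area follows from
pixel counts alone:

    LA = PNL x S_c / PNC                                            [mm^2]

with PNL the leaf pixel count and PNC the calibration-square pixel count.
Measurement accuracy against a standard area S is the relative error
|S - S_t| / S x 100 %; the signed variant keeps the sign of (S_t - S), so
under-measurement is negative.

Two competing protocols are modeled for comparison. *Stretching* flattens the
leaf with five margin clips: the clips occlude tissue, so the observed
silhouette under-counts the leaf and the signed error is negative.  *Manual*
is a hand-held frontal photograph: imperfect perpendicularity and leaf folds
inflate the apparent silhouette, so the signed error is positive. The splint
protocol has neither artifact; with a good segmenter its error is bounded by
rasterization alone.

## Segmentation network

The segmenter is a U-Net: an encoder of `depth` levels (default 5), each two
same-padded 3x3 convolutions + ReLU followed by 2x2 max pooling, mirrored by
a decoder of bilinear 2x upsampling, concatenation of the corresponding
encoder skip feature, and two 3x3 convolutions, closed by a 1x1 convolution
and a two-class softmax. Channel width doubles per level from
`base_channels` (16 by default; 64 would be the full-scale VGG16-style
width — the reduced width trains in minutes on one CPU core and is ample for
the synthetic imagery).

The attention variant inserts a squeeze-and-excitation (SE) block on every
encoder skip feature immediately before concatenation: gates
`sigmoid(FC2(ReLU(FC1(GAP(f)))))`, with FC1 reducing channels by
`se_reduction` (default 16, floored at one unit). Gates are strictly in
(0, 1), so gated features are channel-wise contractions of their inputs; a
`pin_gates` switch bypasses the block (gate = 1), which makes the attention
network reproduce the plain U-Net bit-for-bit — the equivalence is asserted
in the test suite. Upsampling is bilinear (fixed half-pixel-center stencil)
rather than learned deconvolution; the choice is immaterial to the
input/output contract and avoids checkerboard artifacts.

The network runs on a small reverse-mode autograd engine written on numpy
(`splintleaf.nn.autograd`): convolution as im2col + GEMM, pooling with
argmax routing, exact-stencil bilinear upsampling, and Adam. All ops are
checked against central-difference numerical gradients in the test suite.
Training on one CPU core covers the full benchmark in a few minutes.

## Objective and training

The loss is soft Dice, `1 - (2 sum(p t) + eps) / (sum(p) + sum(t) + eps)`
with `eps = 1e-6` so empty-vs-empty scores 1 (loss 0). A per-pixel
`weight_map` hook exists for boundary-emphasis schemes but is off by
default: no concrete weighting scheme is part of the method, so the plain
objective is the defined behavior.

Adam with learning rate 3e-4 is the default. At 1e-3 the small network can
collapse into an all-background prediction from which the Dice gradient
cannot recover (the softmax saturates); 3e-4 trains stably across the seeds
exercised in the tests. Batches are drawn by a seeded shuffle; training is
bit-reproducible on CPU for a fixed seed, and the checkpoint with the best
validation Dice is kept.

Evaluation aggregates TP/FP/FN/TN over all pixels of a split before any
ratio is taken (micro-averaging; the alternative macro-average over images
is not reported). Per-class IoU is TP/(TP+FP+FN) with roles swapped for
background; mIoU is their mean. Mean pixel accuracy (mPA) is the mean of
per-class accuracies and is reported separately from overall pixel
accuracy. Recall is TP/(TP+FN); a variant with TP+TN in the denominator —
a form that appears in print but conflicts with the standard definition —
is available behind `printed_recall_variant` and is never the default.
When a class is absent from both prediction and truth, its undefined
ratios score 1 and the report is flagged.

## Synthetic data

No public imagery exists for this acquisition setup, so the generator is a
first-class, tested component. It emulates: one leaf per frame on a light
background; a reserved-color (saturated magenta) calibration square in the
top-left corner; day/night illumination (night darkens the scene and adds a
lamp gradient); macronutrient-deficiency appearance — global yellowing (-N),
marginal yellowing (-K), patchy yellowing (-Mg), margin curl distortion
(-P); Gaussian sensor noise; and the per-method observation artifacts
described above (five clip occluders for stretching; a mild projective tilt
plus fold shading for manual, re-stamping the marker afterwards since the
board lies in the camera frame).

Leaf outlines are Fourier-perturbed ellipses (3-8 harmonics over an ellipse
of aspect 0.65-0.95), which are smooth, leaf-like, and carry an exact
shoelace polygon area; masks are rasterized by a pixel-center-in-polygon
rule (0-based indices, origin top-left). Rasterized and analytic areas
agree within 2 % for every generated sample — this is a tested invariant,
not an assumption. The ground-truth area is defined as the unoccluded mask
pixel count x mm_per_pixel^2, standing in for a destructive scanner
measurement.

Default study conditions: 128 x 128 px frames at 0.25 mm/px (the 5 mm
calibration square is then 20 px on a side, 400 px), leaf areas drawn
uniformly from 150-450 mm^2 (2,400-7,200 px — large enough that
rasterization error is negligible, small enough to always clear the
calibration corner), noise SD 4 intensity units, clip radius 5 px.
`generate_dataset` cycles samples round-robin through the five nutrient
treatments, mirroring a balanced acquisition design, and assigns
train/val/test splits by a seeded permutation with largest-remainder sizes
(1,080 samples at 6:2:2 give exactly 648/216/216).

What the generator does *not* emulate: real leaf texture and venation,
specular highlights, soil/pot clutter, camera distortion, motion blur, and
the appearance of a physical calibration board (detection by reserved color
is a synthetic-only convenience; real images must supply an explicit
calibration rectangle, and the pipeline fails loudly rather than guessing).
Passing tests therefore demonstrate the correctness of the measurement
chain and the trainability of the network, not field performance on real
imagery.

## Area pipeline numerics

Binarization threshold 0.5 with ties to foreground. Hole filling treats the
background as 4-connected (scipy's default cross structuring element);
foreground components are 8-connected — the standard digital-topology
pairing. Holes are filled *before* the largest component is selected so a
leaf split by a bright specular band is not half-discarded. Component-size
ties keep the component first encountered in raster order. An empty mask
propagates as a flagged zero-area measurement rather than an error.

## Benchmark and sizes

The standard benchmark (`splintleaf.benchmark.run_benchmark`, also behind
`scripts/acceptance.py`) uses 200 splint-method samples at 128 x 128, a
6:2:2 split (120/40/40), the depth-5, base-16 attention U-Net, Adam 3e-4,
batch size 4, and 6 epochs — by which point validation Dice has plateaued
(greater than 0.97 from epoch 4 on, changing only in the third decimal).
These sizes keep a full run in single-digit minutes on one CPU core while
leaving the conclusions unchanged at larger scale. The growth monitor's
relative-growth definition is anchored to day 1,
(area_d - area_1)/area_1 x 100 %, with day-over-day increments as a
secondary output; any biological effect of the clamping itself is a
property of plants, not of this software, and is deliberately not asserted.

## Known limitations

* The autograd engine supports exactly the ops the network needs; it is not
  a general deep-learning framework (no GPU, no mixed precision).
* Reduced width (16 channels) and synthetic imagery mean reported metrics
  are analogues of, not substitutes for, results on real leaves.
* The manual-method artifact model (single projective tilt + sinusoidal
  fold shading) captures the sign and rough magnitude of the bias, not the
  full variability of hand-held photography.
* Calibration by reserved color assumes the synthetic marker; real-image
  calibration requires a user-supplied rectangle.
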