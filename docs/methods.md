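# Methods

This note records the modelling assumptions, the numerical conventions, and
the design choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Compute core

The package carries its own reverse-mode autodiff tape over NumPy arrays
(`yolop.nn`). Convolution is im2col (`sliding_window_view`) plus einsum, so
the heavy lifting stays in BLAS; grouped and depthwise convolutions share
one code path. The tape preserves float64 when given float64 inputs (used
by the gradient tests); model parameters are float32. Batch normalisation
uses eps 1e-3 and momentum 0.03; convolution weights are He-normal
initialised; the objectness bias starts at −4.5 so that initial confidences
are near zero and the confidence loss starts close to its all-negative
floor. Training clips the global gradient norm at 10.

## Architecture

Backbone stages and the block families are described in the README. Points
that were open and how they were fixed:

* **Inverted bottleneck direction.** The inverted shuffle block's branch
  *reduces* the width first (ratio `t` < 1), filters depthwise, then
  expands back with a linear 1×1 convolution. Two observations force this
  reading: the design intent is the mirror image of a CSP-DarkNet residual
  (which widens first), and the ablation ordering — an all-inverted
  backbone must be *cheaper* than an all-shuffle one — only holds when the
  branch narrows. The final projection of every branch in this block is
  linear: a nonlinearity on a low-dimensional projection discards
  information.
* **Activations.** CBH units and the whole neck use Hard-Swish
  (`x·min(max(x+3,0),6)/6`), bounded below by −0.375 and identity above 3.
  Depthwise convolutions carry BN but no nonlinearity and shuffle-block
  pointwise convolutions use the block's activation, both ShuffleNetV2
  conventions. The baseline and the T1–T3 ablations use SiLU.
* **CBAM.** Reduction ratio 16 (8 in the tiny preset), shared two-layer
  perceptron for the average- and max-pooled vectors, 7×7 spatial
  convolution, all attention layers bias-free, and a residual add of the
  refined map onto the input. Channel attention strictly precedes spatial
  attention.
* **Stage repeats and bottleneck ratio.** The per-stage repeat counts and
  `t` are figure-only information in the source material; the printed
  compute/volume accounting is the only hard constraint. `scripts/
  calibrate.py` enumerates (n2, n3, n4) ∈ [8,13]×[5,11]×[1,4] and
  t ∈ {1/3, 1/2, 2/3} and scores each candidate by its worst relative error
  against the three published figures (10.1 GFLOPs, 8.3 MB, 39.4% volume
  reduction). The winner — repeats (11, 9, 1), t = 1/2 — is frozen in
  `yolop.assembly` and is not revisited. A deep-stage-light, shallow-stage-
  heavy profile is also what the design motive (cheap high-resolution
  capacity for small fruit) predicts.
* **Ablation variants.** T1/T2 replace all four backbone groups with
  shuffle / inverted blocks; they need a stage-1 repeat count, which is
  taken equal to n2. T3 is the mixed backbone with SiLU and no CBAM, T4
  swaps in Hard-Swish, and the full model adds CBAM.
* **Anchors.** YOLOv5 defaults at 640 input; `kmeans_anchors` refits them
  to a label set (plain Lloyd's algorithm, clusters sorted by area into
  three scales). Desk-scale runs always refit.

## Accounting conventions

* **FLOPs.** `count_macs` sums, over convolutional layers only,
  `L² · K² · C_out · C_in/groups` with `L` the output spatial side —
  i.e. multiply-accumulates; `count_flops` doubles it (multiplications +
  additions), the convention of standard profilers and of the published
  totals this package reproduces. Shapes are resolved by running the model
  once at a 64-pixel reference input and scaling the recorded spatial
  sides, which is exact because every layer's extent is input/stride.
* **Model volume.** `serialized_volume` writes every learnable parameter
  and batch-norm statistic as little-endian float16 into a single archive
  (a small JSON manifest of names/shapes, then the raw payload) and reports
  the measured file size in binary megabytes (2^20 bytes) — the unit file
  browsers display for weight files. Training checkpoints use the same
  container at float32 so that save/load is bit-exact.

## Loss

Per scale, every anchor×cell prediction contributes to the confidence BCE
(the normaliser N is the full prediction count at that scale); matched
predictions carry a soft objectness target equal to their CIoU with the
assigned ground truth clamped to [0,1] (a config switch restores plain
IoU), negatives carry 0. Per-scale losses are combined 6.0/1.0/0.5
(small/medium/large); these weights *replace* any per-scale balancing —
none is stacked on top. The location loss is the mean CIoU loss over
matched predictions; α is computed in-graph (the formula's literal
gradient), with an 1e-9 guard for the IoU = 1, v = 0 corner. Box decoding
uses sigmoid offsets `(2σ−0.5)` and `(2σ)²`-scaled anchors. Assignment is
shape-ratio gated (max ratio < 4) at the centre cell plus the two nearest
neighbour cells.

One consequence, verified while testing: because the objectness targets
follow the predictions, the total loss on a frozen batch *rises* for the
first ~15 optimiser steps (box improvement raises the soft labels) before
descending; the stationary location term decreases monotonically from the
start. The descent tests check exactly that.

## Evaluation

Greedy NMS (descending confidence, ties to the earlier index, default IoU
0.45). Matching discards detections below confidence 0.4, then greedily
pairs survivors with the unmatched ground truth of highest IoU ≥ 0.5.
P/R/F1 use the convention 0 when a denominator is 0. AP@0.5 integrates the
all-point precision envelope (an 11-point option exists); with one class,
AP = mAP. Stratified reports pool counters over images (not per-image
averages). Shade is an object-level axis: TP/FN go to the ground truth's
category; an unmatched detection is attributed to the shade category of
the ground truth it overlaps most in its image, or to "untagged" when it
overlaps none. Fruit with K_s ≥ 0.6 are excluded from matching and
reporting by default.

## Synthetic scenes

The generator emulates the *controlled factors* of orchard imagery, not its
appearance: low-frequency green-brown backgrounds with leaf/branch clutter,
elliptical fruit with radial shading and a highlight, leaf-like occluders,
and a night mode (directional luminance gradient, cast-shadow band, slight
blue shift). Camera distance is unobservable in a renderer, so the three
background-complexity tiers map to on-image fruit diameter bands — 120–200 /
60–120 / 20–60 px at a 640 canvas, scaled linearly with canvas size — plus
increasing clutter density; the bands are disjoint by construction.

Shade degree is controlled, not assumed: an occluder (area ≈ 1.6·K_s times
the fruit, at least 0.45) slides toward the fruit centre by bisection on
the *measured* mask overlap until within ±0.02 of the request (40
iterations; unattainable targets raise an error naming the object). The
recorded K_s of every object is recomputed exactly from the rendered masks,
so evaluation strata are noiseless. Fruit are placed without mutual
overlap (occluders are the only shading source); a post-check rejects
scenes where a neighbour's occluder drifts another fruit's K_s out of
tolerance. Boxes are amodal (full fruit extent).

Dataset defaults mirror the real dataset's composition: tier weights
0.23/0.31/0.46, night fraction 0.30, K_s sampled 45% slight / 30% medium /
25% serious (all < 0.6), and an 8:2 shuffled train/val split
(round(0.8·n)). Augmentation picks 3 distinct strategies of 6 per image —
flips at probability 0.5 each, scaling U(0.80, 0.95) with canvas padding,
brightness U(0.35, 1.50), Gaussian blur, Gaussian noise; geometric ops
transform boxes, clipped boxes keeping < 10% area are dropped and logged.
All randomness flows from one seed; per-image seeds come from
`SeedSequence`.

What passing on synthetic scenes does **not** show: robustness to real
foliage texture, specular highlights, camera noise, motion blur, mutual
fruit occlusion, or any specific camera. The renderer validates the
pipeline (architecture, loss, assignment, NMS, AP, stratification), not
field performance.

## Training runtime

Adam with β1 = 0.9 (the recipe's "momentum decay"; it names SGD vocabulary
while using Adam, so β1 is the only sensible target), decoupled weight
decay 5e-4 applied to weight tensors only, initial LR 0.01, 3-epoch linear
warmup from 0.1·LR during which β1 ramps from 0.8, cosine decay to 0.01·LR
at the final epoch, batch size 32, up to 500 epochs, early stop after 50
epochs without validation-AP improvement (validation AP@0.5 is the
"accuracy" the stopping rule watches). The desk-scale smoke schedule
(`smoke_train_config` / `smoke_dataset`) uses 16 near-tier 96-px scenes,
batch 8, 300 epochs, evaluation every 10 epochs, and the quarter-width
`tiny_spec` preset with repeats (1, 2, 1) — sized so the whole run takes
about a minute on one CPU core.

## Known limitations

* Inference speed (FPS) is hardware-bound and deliberately not asserted.
* The NumPy core is single-threaded beyond BLAS; full-scale 640-px
  training is out of desk scope by design.
* Letterbox resize only; mosaic augmentation is off by default (a config
  switch exists in spirit via the augmentation menu, which does not include
  it).
* The calibrated stage repeats/bottleneck ratio reproduce the published
  accounting but are not guaranteed to equal the original figure-only
  values; any configuration matching all three printed constraints is
  observationally equivalent at this level.
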