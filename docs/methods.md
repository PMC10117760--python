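# Methods

`neuroseg2` segments neuronal somata in motion-corrected two-photon Ca²⁺
imaging movies. The pipeline has four parts: spatiotemporal image fusion,
a two-stage detection network with channel attention and an augmented
feature pyramid, staged training with cross-validation protocols, and
Hungarian-matching evaluation, plus tiled inference for fields of view that
exceed the network input. This note records the model, its assumptions, the
defaults and the open design choices.

## Image fusion

A movie `T×H×W` is collapsed into a single network input in three steps.

**Average projection** — the per-pixel temporal mean. It shows anatomy
(baseline fluorescence) but hides sparsely firing neurons whose baseline
sits at the background.

**Correlation map** — each pixel scores the coherence of its neighbourhood's
temporal traces:

```
c_w(f_1, f_2, …) = ‖Σᵢ aᵢ fᵢ‖₂ / Σᵢ aᵢ ‖fᵢ‖₂
```

with `fᵢ` the traces in a Gaussian-weighted window and `aᵢ > 0` the
weights. Cauchy–Schwarz plus the triangle inequality bound `c_w` in
`[0, 1]`; identical traces give exactly 1, incoherent ones give small
values, so co-fluctuating somata light up even when anatomy-invisible.
Defaults: window radius 3 px, σ = 1.5 px (local relative to 10–30 px
somata). Traces are temporally centred first (`center_traces=True`,
exposed as a flag): without centring the shared baseline drives `c_w → 1`
everywhere. The neighbourhood is truncated at image borders — equivalent to
renormalising the weights, since `c_w` is invariant to their common scale —
and a pixel whose whole neighbourhood has zero-norm traces gets `c_w = 0`
(a dead pixel carries no evidence). The map is invariant to frame
permutation: it is a per-pixel statistic over time.

**Fusion** — no specific arithmetic is canonical for combining the two
images, so the package documents one: each image is min–max normalised to
`[0, 1]` independently (a constant image maps to zero, with a warning) and
combined convexly, `alpha·avg + (1−alpha)·corr`, `alpha = 0.5` by default
and exposed in `FusionConfig`.

**Segment splitting** — one video becomes `n + 1` fused images: `n`
contiguous equal temporal segments (the `T mod n` leftover frames go to the
earliest segments, a deterministic order-preserving rule) plus the whole
video; the default `n = 6` yields seven images per video. Single-frame
segments have no temporal structure; their correlation map is identically
zero.

## Synthetic data

The generator renders the structure the method exploits, with ground truth:

* **Donut somata** — cytoplasmic indicator expression makes the ring
  brighter than the nuclear hole. Rendered as an annulus (hole level 0.3 of
  ring level, hole radius = `ring_fraction`·radius) smoothed by a σ = 1 px
  Gaussian to avoid aliasing. GT masks are the filled disks.
* **Activity** — Poisson event trains convolved with an exponential decay
  kernel (`tau` = 5 frames). Active neurons get transients; inactive
  neurons keep a static baseline above background (anatomy-visible,
  activity-invisible).
* **A sparse neuron** — one active neuron, chosen outside the overlap
  pairs, has its baseline set to the background so it is invisible in the
  average projection (< 1.2× background contrast at the defaults) yet
  clearly visible in the correlation map (> 1.5× off-mask mean). It is
  guaranteed at least a few events. Forcing it active can raise the active
  count by one above `round(active_fraction·n)`.
* **Overlap pairs** — partner somata placed ≈ 1.1 minimum-radius from their
  mates so the disks share pixels; all other placements are
  rejection-sampled with a minimum separation large enough that no
  unintended pair touches.
* **Noise** — additive i.i.d. Gaussian (`noise_sigma = 2` intensity units
  on a background of 20).

Defaults: 128×128 px, 200 frames at 10 Hz (a typical two-photon frame
rate), 12 neurons of radius 5–8 px, 60 % active at 0.2 events/s. The
generator does **not** model neuropil contamination, photobleaching or
motion artifacts; passing tests therefore demonstrate correctness of the
pipeline mechanics and the average-vs-correlation phenomenology, not
performance on real tissue.

## Network

A Mask R-CNN-style two-stage detector, configurable per ablation arm from
`ModelConfig` alone:

* **Backbone** — ResNet-style stages emit C2–C5 (strides 4–32); with
  `path_augmentation` an extra stride-2 convolution after C5 adds C6, so
  the backbone emits five levels instead of four.
* **FPN** — 1×1 lateral projections fused top-down with nearest-neighbour
  upsampling. `fusion_up` is `add` (element-wise, channels preserved) or
  `concat` (channels stacked, always followed by a CSP layer). The
  reference configuration uses add up, concat down.
* **ECA** on every lateral connection (`attention="eca"`): global average
  pooling, a bias-free 1-D convolution of odd length `eca_kernel`
  (default 3, fixed for deterministic parameter accounting) and a logistic
  gate per channel. Each instance adds exactly `eca_kernel` parameters, so
  the attention-vs-none parameter delta is `(number of lateral
  connections) × eca_kernel`. CBAM is available as a comparison arm, not
  tuned.
* **FPN+** — a second, bottom-up path: Y2 = P2, then each coarser Y fuses a
  stride-2 down-sampling of the previous Y with a lateral (attention-gated)
  1×1 projection of the corresponding P via `fusion_down`, giving Y2–Y6.
  The exact lateral wiring is not canonical; per-level 1×1 projections
  from the FPN outputs is the documented resolution.
* **CSPLayer** — split into two half-width 1×1 branches, one passing
  through `csp_depth` (default 1) residual bottlenecks, re-concatenated and
  projected; applied after every concat fusion.
* **Heads** — a shared-across-levels RPN (3×3 conv, objectness + box
  deltas per anchor), ROI-Align (one bilinear sample per bin; 7×7 for the
  classification/regression branch, 14×14 for the mask branch), a
  two-layer MLP box head with a single-logit classifier (one foreground
  class), and a convolutional mask head upsampled to 28×28 logits.

Defaults the architecture description leaves open, fixed here: backbone
depth selector (10/18/34 basic-block layouts, default 18), anchor scales
{8, 16, 32, 64, 128} px with ratio 1 (covering 10–30 px somata across
levels), input canvas 512 px (zero-padded, never rescaled — detections map
back by cropping), score threshold 0.5, mask binarisation 0.5, at most 500
instances (fields of view hold ~100–400 neurons), SGD with momentum 0.9 and
weight decay 1e-4. ROIs up to twice the finest anchor scale are cropped
from the stride-4 level — small somata need the highest-resolution
features for mask quality — with one level coarser per octave. Mask
targets are sampled at exactly the ROI grid's bin centres and predictions
are pasted back with the inverse mapping, so no half-pixel misalignment
enters the mask loss. Box NMS is followed by a mask-level deduplication at
the same IoU threshold, since two boxes can overlap weakly while their
masks coincide.

The loss is the sum of five nonnegative terms: RPN objectness (binary
cross-entropy on a sampled, positively-biased anchor set; the best anchor
per GT box is forced positive), RPN box regression (smooth-L1 on
positives), ROI classification (BCE), ROI box regression (smooth-L1 on
foreground), and mask BCE on foreground ROIs. GT boxes are appended to the
proposal set during training so the heads always see foreground. A
non-finite loss aborts with the offending component named.

The network runs on an in-package reverse-mode automatic-differentiation
engine over numpy arrays (float32), with convolution via im2col. It is
exact (finite-difference-checked) but CPU-bound, so tests and the
acceptance script use a reduced configuration: depth 10, 8 base channels,
16 pyramid channels, 128 px canvas, anchors {8, 16, 24, 32, 48}. Every
architectural component is still present.

## Augmentation

Five operations: horizontal flip, vertical flip, rotation by 90/180/270°,
isotropic scaling in [0.8, 1.5] (bilinear image, nearest-neighbour masks,
re-cropped/padded to the original canvas), and additive Gaussian noise with
σ uniform in [0, 5] interpreted on the 0–255 intensity scale. Per call a
count `k ~ U{0..max_ops}` is drawn, `k` distinct operations are chosen and
applied in a fixed canonical order (geometric before noise) for
reproducibility. Geometric operations transform image and masks
identically; noise touches only the image. A mask emptied by scaling is
dropped and logged.

## Training

Stages freeze or thaw parameter scopes. The "heads" scope is the
classification/regression and mask branches; the RPN is trained only in
whole-network stages (the precise layer boundary of "head" is a documented
choice). Two reference schedules are built in: the hybrid schedule
(50 head-only epochs at 1e-3, then 100 whole-network at 2e-4 and 50 at
1e-4; 500 steps/epoch, batch 2; 200 epochs total) and the benchmark
schedule (20 head-only + 130 whole-network epochs at 1e-3; 50 steps/epoch,
batch 2; 150 total). Parameters outside the active scope are bit-identical
across a stage. Training is deterministic given the schedule seed.

Cross-validation: *two-round hybrid* splits the groups into halves; each
half's test items are scored by a model trained on the union of the other
half's training items, so every group is tested exactly once on held-out
data. *N-round single* trains one model per group on its own training
items. Transfer learning is supported by loading a locally supplied
checkpoint (`--init-weights`); the default is random initialisation.

## Evaluation

Masks are pixel sets. `IoU = |m₁∩m₂| / |m₁∪m₂|`; the assignment cost is
`1 − IoU` when `IoU ≥ 0.5` *or* one mask contains the other, else infinite.
The containment clause is read as a disjunction — the only reading under
which it is not redundant. The Hungarian algorithm minimises total cost;
infinite entries are replaced by a finite sentinel larger than any total
finite assignment (finite costs are < 1 each, so `min(n,m)+1` suffices —
the sentinel provably never displaces a finite match) and sentinel pairs
are dropped. Matched pairs are the true positives; precision
`N_TP/N_detected`, recall `N_TP/N_GT`, F1 their harmonic mean, all zero
under the conservative zero-division convention. Reports display 4
decimals.

## Tiling

Oversized images are covered by `ceil(H/stride) × ceil(W/stride)` tiles,
`stride = tile − overlap`, border tiles clipped. The default 100 px/0-px
grid splits a 1,682×1,792 px mesoscopic canvas into exactly 17×18 = 306
tiles. For operation an overlap of ~20 px (one soma diameter) is
recommended so border-straddling somata are seen whole by some tile;
translated duplicates with IoU ≥ 0.5 are merged by pixel union, keeping
the higher score. How split neurons should be recombined is not canonical;
overlap-plus-union-merge is this package's documented resolution.

## Problem sizes and limitations

The test suite and acceptance script train the reduced network on one or
two 128 px synthetic scenes for ~700 SGD steps (about a minute on one CPU
core); that suffices for the overfit-recovery, freeze-contract,
loss-descent, flip-equivariance and tiling-consistency checks. These runs
demonstrate the machinery end to end; they say nothing about segmentation
accuracy on real recordings, which requires training at full scale on
annotated data. The overfit toy model is translation-sensitive (it has
seen one scene), so the tiling consistency check uses tile offsets aligned
to the coarsest feature stride. Flip equivariance is asserted as a sanity
bound (mean matched mask-IoU ≥ 0.9 between a scene and its mirror) rather
than exactness, because convolution kernels are not mirror-symmetric.
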