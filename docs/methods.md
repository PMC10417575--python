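# Methods

This note documents the modeling and numerical choices behind
`vesselseg`: the network family and its parameter accounting, the
sparse-label loss, the training schedule, the data pipeline, and what
the synthetic benchmark does and does not demonstrate.

## Problem setting

Stained histological sections of vascularized (tumor) tissue are
segmented into six classes — background, tissue, destroyed tissue,
debris, vessel wall, vessel lumen. Annotation is *sparse*: an
annotator draws strokes, every untouched pixel carries the sentinel
value 255, and loss and metrics are computed over labeled pixels only.
Slides of arbitrary size are handled by mirror-padding to a multiple
of 128 px, tiling into non-overlapping 128 × 128 patches, processing
patches independently, and stitching the outputs back (the grid
manifest makes the round trip bit-exact; no overlap blending is used).

## Network family

One `ArchitectureConfig` selects a member of the ablation grid. The
baseline is a four-level U-Net: encoder widths 64, 128, 256, 512, a
1024-channel bridge, and a mirrored decoder. A *unit* is a same-padded
biased 3×3 convolution, channel normalization, ReLU; a *block* is two
units; downsampling is 2×2 max pooling; upsampling is a biased 2×2
stride-2 transposed convolution without normalization; the head is a
biased 1×1 convolution to six channels with a per-pixel softmax.
Dropout (rate per variant) is applied after each encoder block's
pooling step and after each decoder block; the skip connections
therefore carry undropped features, which keeps the skip pathway
informative at high rates.

Mechanisms, each independently switchable:

- **Residual links.** A biased 1×1 projection with channel
  normalization bypasses both units of a block and is summed in before
  the block's final activation. A projection is used whenever input
  and output widths differ (in this family: always).
- **Attention gates.** Additive gates on each skip: the skip tensor
  `x` and the upsampled decoder signal `g` (equal widths `F`) are
  projected by biased 1×1 convolutions to an internal width (default
  `F`), joined, passed through ReLU and a biased 1×1 scalar map, and
  the sigmoid coefficient rescales `x` pixelwise. The internal width
  is configurable.
- **Recurrent links.** Each unit is unrolled `recurrence_steps` times
  (default 3) sharing its 3×3 kernel; feedback enters through a
  dedicated biased 1×1 convolution:
  `h_1 = act(norm(conv(x)))`, `h_t = act(norm(conv(x) + rec(h_{t−1})))`.
  Normalization is shared across steps. With one step the unit is
  bit-identical to the plain unit. Unrolling multiplies each unit's
  contribution to the receptive field, which the closed form
  `r0 = 1 + Σ (k_l − 1)·Π s_i` quantifies (21 px → 61 px for the
  ten-unit stack at three-fold unrolling); the closed form is verified
  against a gradient-mask oracle in the tests.

### Parameter accounting and calibration

"Stored parameters" counts every persisted scalar: trainable weights
plus the normalization layers' moving statistics (four scalars per
normalized channel — scale, shift, moving mean, moving variance).
Under this convention the baseline stores exactly **31,055,622**
scalars and the residual variant exactly **32,463,174** — both
matching the reference totals for this architecture family to the
digit, which is what fixed the otherwise unprinted design choices
(widths, biases, where normalization sits, transposed-convolution
upsampling). The published attention and recurrent totals
over-determine no single gate/recurrent wiring: an exhaustive search
over gate grammars (kernel sizes 1–3, internal widths from F/8 to 2F
and constants, bias/normalization placements, optional output
transforms, gating taken before or after upsampling) found no
structurally sensible configuration reproducing them exactly. The
defaults here land at 31,754,826 (attention, 0.08 % below the
reference total) and 34,551,302 (recurrent, 3 % below) and preserve
the reference ordering baseline < +attention < +residual < +recurrent,
with every combination exceeding the baseline additively.

### Initialization and determinism

Weights are He-initialized (fan-in-scaled normal) from a seeded
generator; biases start at zero. A checkpoint archives all weights,
buffers, the full architecture config and the seeds, and restoring one
reproduces forward passes bit-for-bit on the same platform. All
randomness in the package flows through `numpy.random.default_rng`
seeds.

## Loss and metrics

Per class `c`, with smoothing σ (default 1e-6, configurable):

    PREC = (TP+σ)/(TP+FP+σ)    RECL = (TP+σ)/(TP+FN+σ)
    SPEC = (TN+σ)/(TN+FP+σ)    DICE = (2TP+σ)/(2TP+FP+FN+σ)

    L = 1 − 3|C| / Σ_c (1/PREC_c + 1/RECL_c + 1/DICE_c)

The `3|C|` numerator is the harmonic mean of the 3·|C| pooled
reciprocals and is the unique normalization for which perfect
segmentation gives L = 0 and the loss spans [0, 1]; as σ → 0, L equals
one minus the harmonic mean of the per-class Dice scores, so a single
dead class drives L to 1. For training, soft counts (predicted
probabilities accumulated against one-hot scribbles) are pooled over
each mini-batch — not per image — before the loss is formed; pooling
stabilizes gradients when single patches miss classes entirely. With
σ > 0 an empty class scores 1.0 on all its metrics (σ/σ), i.e. an
absent class is treated as perfectly handled. With σ = 0 a 0/0 metric
is reported as NaN, never silently as 0.

Evaluation pools hard-argmax counts over the whole evaluation set
(micro per class) and reports per-class values plus unweighted macro
means. One-vs-rest ROC curves are computed per class from the class's
predicted probability against the membership indicator over all
labeled pixels (scikit-learn `roc_curve`, trapezoidal AUC); the macro
AUC is the unweighted mean over classes with at least one positive and
one negative pixel, degenerate classes being excluded and reported.
Whether a "total" AUC should be macro- or pixel-micro-averaged is not
determined by the source material; macro was chosen and is flagged
here.

## Training schedule

Adam (β = 0.9/0.999, ε = 1e-8), initial learning rate 1e-4, batch 16,
maximum 300 epochs — the defaults of the study conditions; desk-scale
runs override them explicitly. The monitored quantity is the
validation loss (train-loss monitoring is a flag; the source material
does not say which drove its plateau events, so both are logged). A
plateau is "no improvement beyond 1e-4 absolute for 10 epochs", where
the first monitored epoch establishes the baseline without counting as
an improvement — this is the reading under which a constant loss trace
produces plateau events exactly at epochs 10, 20, 30, 40. Each
plateau multiplies the learning rate by 0.1 and restarts the patience
window; an improvement resets the consecutive-plateau counter; the
fourth consecutive plateau stops training. The best-validation
checkpoint is retained. The schedule logic is a standalone state
machine (`PlateauSchedule`) checked event-for-event against an
independent re-implementation on scripted traces.

Hard-example mining ranks labeled patches by their individual sparse
loss (restricted to the classes actually scribbled on the patch) so
the top of the list can be exported for re-labeling.

The hyperparameter grid spans batch sizes {1,2,4,8,16,32}, dropout
{0, 0.125, 0.25, 0.375}, learning rates {1e-2, 1e-3, 1e-4} and the
three mechanism toggles — 6·4·3·2³ = 576 combinations, enumerated
deterministically; `GridBudget` caps epochs, model size and subset
size per cell, and finished rows are skipped when re-run against an
existing results file.

## Augmentation

Each training patch is augmented (default 10 draws per patch, the
originals not re-included, so 4,500 patches yield 45,000): contrast
scaling about the image mean with factor in [0.1, 1.9] ("±90 %"),
additive brightness in ±0.3 of full scale, independent per-axis zoom
in [0.5, 2], rotation in ±90°, and one of {no flip, horizontal,
vertical}. Flip, rotation and zoom are composed into a single centered
affine and applied in one resampling pass — bilinear for the image,
nearest-neighbor for the mask (no interpolated class labels, sentinel
preserved), mirror fill for exposed regions, output cropped to
128 × 128. Photometric operations touch the image only and are clipped
to [0, 1]. The operator definitions (multiplicative contrast about the
mean, additive brightness) are this package's reading of the stated
ranges; both the order of operations and the ranges are configuration.
Augmentation is precomputed (the fixed ×10 total suggests so); an
on-the-fly path is available by drawing inside the training loop.

## Synthetic benchmark

The generator targets the *statistics* the method is sensitive to, not
visual fidelity to immunohistochemistry: a wobbly tissue blob on a
near-white background rim (background always touches the canvas
edges), elliptical vessels whose continuous wall rings (thickness ≥ 1
px, default 3–6 px) enclose pale lumina with dark cell speckles that
remain lumen in the truth, dark heterogeneous destroyed-tissue
patches, compact debris blobs, smooth tissue texture, and global
staining drift (linear brightness plane plus a contrast gradient).
Class frequencies reproduce the characteristic imbalance
(tissue > background > lumen > wall ≫ debris). Vessels are rasterized
from a continuous elliptical radius field, so walls are closed rings
by construction; a flood-fill test verifies that no lumen reaches
tissue without crossing wall.

The scribble sparsifier follows the labeling rules of the sparse
protocol: walls copied completely; each lumen given an inner rim line
plus crossing lines that traverse the speckles; a tissue line marks
the outer side of each wall; long strokes across tissue and
background, the latter including a line along the tissue border; small
marks on destroyed tissue and debris so every class is supervised.
Every selected pixel set is intersected with its own class region, so
scribble/truth consistency is exact by construction (and asserted).
Under the default policy roughly 10–15 % of pixels are labeled on a
512² scene. The real labeled fraction per patch of the original
protocol is not quantified anywhere; the default policy aims at
modest per-class budgets and is fully configurable.

What passing on this benchmark shows: the loss, sparse supervision,
optimization, and architecture plumbing work end to end, and scribble
supervision suffices to recover dense structure when class appearance
is separable. What it does not show: performance on real stained
tissue, whose intra-class heterogeneity, staining chemistry and
annotation noise the generator deliberately does not model; nor
robustness to serial-section continuity, which is not simulated.
Because the scenes are chromatically separable, small models saturate
near the benchmark's ceiling within a few dozen epochs; once there,
differences *between* architectural mechanisms (e.g. attention versus
baseline) are within seed noise on this benchmark, so mechanism
orderings measured on it are not evidence about their ordering on
heterogeneous real tissue — the tests reflect this honestly rather
than paper over it.

## Desk-scale problem sizes

The shipped tests and examples use sizes chosen for a single CPU core:
six 256² scenes (24 patches, 16/4/4 split), a two-level width-8 model,
batch 8, learning rate 1e-2, and 30 epochs for the learning smoke
test; the schedule, loss and geometry oracles run on scripted traces
and toy tensors. The full-size four-level networks are built for
parameter accounting and shape checks; training them end-to-end is
supported but sized for real workstations.

## Known limitations

- The split is patch-level, mirroring the original protocol; with
  serial sections this risks information leakage between nearly
  identical adjacent patches, and slide-level splitting should be
  preferred when slide provenance is available.
- The train/validation/test naming here is the conventional one
  (60/20/20 = train/val/test); the source material's phrasing orders
  the 60-20-20 fractions as "training, test, validation", and the
  mapping is fixed by this package's `DataConfig`.
- Attention-gate internals and recurrent-path wiring are calibrated
  choices, not uniquely determined (see parameter accounting above).
- The numpy engine is single-threaded apart from BLAS matmuls; it is
  meant for correctness, desk-scale experiments and tests, not for
  full-slide training throughput.
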