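# vesselseg

Semantic segmentation of blood vessels in histologically stained tumor
sections, trained from **sparse scribble annotations**. The package
implements a configurable U-Net family (attention gates, residual
links, recurrent links, dropout), a harmonic-mean multiclass Dice loss
over six tissue classes, the patch/augment/split data pipeline, a full
evaluation suite (per-class metrics, one-vs-rest ROC/AUC), and a
synthetic vessel-scene generator with a scribble sparsifier so the
whole method can be trained and tested at desk scale without access to
clinical slides.

## Who this is for

Groups that need pixel-accurate delineation of vessel walls and lumina
in stained whole-slide images — e.g. for quantifying tumor
vascularization or reconstructing vascular networks for 3D in-vitro
models — but cannot afford dense pixel-level annotation. Scribble
labels (a few strokes per structure) plus an ignore-sentinel in the
loss reduce annotation effort by an order of magnitude.

## The model

Images are cut into 128 × 128 px RGB patches and mapped to per-pixel
probabilities over six classes: background, tissue, destroyed tissue,
debris, vessel wall, vessel lumen. The backbone is a four-level
encoder/decoder U-Net (widths 64→128→256→512, 1024-channel bridge),
each block being two units of (3×3 convolution, channel normalization,
ReLU) with 2×2 max pooling down and 2×2 stride-2 transposed
convolutions up. Three mechanisms can be switched on independently:

- **attention gates** — additive gates that reweight each skip
  connection by its relevance to the upsampled decoder signal;
- **residual links** — a biased 1×1 projection (plus normalization)
  bypassing both units of every block;
- **recurrent links** — each unit unrolled *t* times with a shared 3×3
  kernel and a 1×1 recurrent-path convolution, which enlarges the
  receptive field: for a stack of layers with kernels `k_l` and strides
  `s_i`, one output pixel sees

      r0 = 1 + Σ_l (k_l − 1) · Π_{i<l} s_i

  pixels per side — 21 px for ten 3×3 stride-1 units, 61 px when each
  unit is unrolled three-fold.

Training minimizes one minus the harmonic mean of smoothed per-class
precision, recall and Dice,

    L = 1 − 3|C| / Σ_c (1/PREC_c + 1/RECL_c + 1/DICE_c),

computed only over scribbled pixels (sentinel 255 = unlabeled). The
harmonic mean punishes any single badly segmented class, which is what
the strong class imbalance of histological data requires. The learning
rate (Adam, 1e-4) is cut ×0.1 whenever the validation loss plateaus
for 10 epochs; four consecutive plateaus stop training (≤300 epochs).

The networks run on a compact numpy tensor engine with reverse-mode
autodiff that ships inside the package (`vesselseg.nn`) — no GPU or
external deep-learning framework is required.

## Worked example

```python
import numpy as np
from vesselseg.architecture import ArchitectureConfig, build_model, count_parameters
from vesselseg.synthetic import make_benchmark
from vesselseg.training import TrainingConfig, train, evaluate

# six synthetic stained scenes -> 24 aligned (image, scribble, dense) patches
bench = make_benchmark(6, seed=11)
train_p, val_p, test_p = bench.patches[:16], bench.patches[16:20], bench.patches[20:]

model = build_model(ArchitectureConfig(levels=2, base_width=8, dropout_rate=0.1), seed=0)
result = train(model, train_p, val_p,
               TrainingConfig(batch_size=8, learning_rate=1e-2, max_epochs=30))
print(result.summary())
report = evaluate(result.restore_best(), test_p)
print("dense macro Dice:", round(report["metrics"].macro()["dice"], 3))
```

prints (30 epochs, a few minutes on one CPU core):

```
dense macro Dice: 0.888
```

i.e. the tiny two-level model recovers ~89 % mean overlap across all
six classes on held-out patches, evaluated against the *dense*
synthetic ground truth even though it was trained only on scribbles.

The same things from the shell:

```
$ vesselseg rf --layers 3x1,3x1 --repeat 5
21
$ vesselseg rf --layers 3x1,3x1 --repeat 5 --unroll 3
61
$ vesselseg params --variant baseline
31055622
$ vesselseg synth --scenes 1 --canvas 256 --out ds
$ vesselseg train --data ds --out run --levels 2 --base-width 8 --epochs 30 \
      --batch-size 8 --lr 1e-2
$ vesselseg predict --image ds/images/scene000_r0_c0.png \
      --checkpoint run/checkpoint.npz --out pred.png --overlay overlay.png
$ vesselseg evaluate --data ds --checkpoint run/checkpoint.npz --out metrics
```

`params` reports the stored-parameter total of a named variant — the
baseline four-level network stores exactly 31,055,622 scalars
(convolution weights and biases plus four normalization scalars per
channel, two of them moving statistics).

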