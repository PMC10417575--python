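"""Sparse-label confusion counting, per-class metrics, the harmonic-mean
multiclass Dice loss, and one-vs-rest ROC/AUC.

All counting excludes pixels carrying the *unlabeled* sentinel, which is
what makes scribble supervision work: the network is only graded on the
pixels an annotator actually touched.

Metrics per class c (sigma is a small smoothing constant):

    PREC = (TP + s) / (TP + FP + s)
    RECL = (TP + s) / (TP + FN + s)
    SPEC = (TN + s) / (TN + FP + s)
    DICE = (2 TP + s) / (2 TP + FP + FN + s)

The training loss is one minus the harmonic mean of precision, recall
and Dice pooled over all classes,

    L = 1 - 3|C| / sum_c (1/PREC_c + 1/RECL_c + 1/DICE_c),

which equals 1 minus the harmonic mean of the per-class Dice scores as
sigma -> 0: perfect segmentation gives L = 0, a single dead class drives
L to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .nn import Tensor

SENTINEL = 255
DEFAULT_CLASSES = tuple(range(6))
DEFAULT_SIGMA = 1e-6


# --------------------------------------------------------------------------
# confusion counting
# --------------------------------------------------------------------------
@dataclass
class ClassConfusion:
    """Per-class TP/FP/FN/TN counts over the labeled pixels."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    classes: tuple = DEFAULT_CLASSES
    sigma: float = DEFAULT_SIGMA

    def __add__(self, other):
        if self.classes != other.classes:
            raise ValueError("cannot pool confusions over different class sets")
        return ClassConfusion(
            self.tp + other.tp, self.fp + other.fp,
            self.fn + other.fn, self.tn + other.tn,
            self.classes, self.sigma,
        )

    def index(self, c):
        return self.classes.index(c)


def _check_mask(labels, classes):
    labeled = labels != SENTINEL
    known = np.isin(labels, classes)
    bad = labeled & ~known
    if bad.any():
        raise ValueError(
            f"mask contains unknown class indices {sorted(set(labels[bad].tolist()))}"
        )
    return labeled


def confusion_counts(
    prediction, labels, classes=DEFAULT_CLASSES, sigma=DEFAULT_SIGMA, mode="hard"
):
    """Count per-class TP/FP/FN/TN against a sparse mask.

    prediction: hard label map with the same shape as ``labels``, or a
    class-probability map with a trailing channel axis.  In hard mode a
    probability map is argmax-reduced; in soft mode probabilities are
    accumulated fractionally (the differentiable convention).
    Sentinel-valued mask pixels contribute to no count.
    """
    labels = np.asarray(labels)
    prediction = np.asarray(prediction)
    classes = tuple(classes)
    has_channels = prediction.ndim == labels.ndim + 1
    if (prediction.shape[: labels.ndim] if has_channels else prediction.shape) != labels.shape:
        raise ValueError(
            f"prediction shape {prediction.shape} does not match mask {labels.shape}"
        )
    labeled = _check_mask(labels, classes)

    k = len(classes)
    tp = np.zeros(k)
    fp = np.zeros(k)
    fn = np.zeros(k)
    tn = np.zeros(k)
    if mode == "hard":
        pred = prediction.argmax(axis=-1) if has_channels else prediction
        if has_channels:
            pred = np.asarray(classes)[pred]
        for i, c in enumerate(classes):
            is_c = labels == c
            pred_c = pred == c
            tp[i] = np.count_nonzero(is_c & pred_c)
            fp[i] = np.count_nonzero(labeled & ~is_c & pred_c)
            fn[i] = np.count_nonzero(is_c & ~pred_c)
            tn[i] = np.count_nonzero(labeled & ~is_c & ~pred_c)
    elif mode == "soft":
        if not has_channels:
            raise ValueError("soft mode requires a probability map")
        for i, c in enumerate(classes):
            p_c = prediction[..., i]
            is_c = labels == c
            other = labeled & ~is_c
            tp[i] = p_c[is_c].sum()
            fp[i] = p_c[other].sum()
            fn[i] = (1.0 - p_c[is_c]).sum()
            tn[i] = (1.0 - p_c[other]).sum()
    else:
        raise ValueError(f"mode must be 'hard' or 'soft', got {mode!r}")
    return ClassConfusion(tp, fp, fn, tn, classes, sigma)


def confusion_matrix(prediction, labels, classes=DEFAULT_CLASSES):
    """Dense (labeled-as-i, predicted-as-j) pixel count table."""
    labels = np.asarray(labels)
    prediction = np.asarray(prediction)
    if prediction.ndim == labels.ndim + 1:
        prediction = np.asarray(classes)[prediction.argmax(axis=-1)]
    if prediction.shape != labels.shape:
        raise ValueError("prediction and mask shapes differ")
    labeled = _check_mask(labels, classes)
    k = len(classes)
    lut = np.full(SENTINEL + 1, -1, dtype=np.int64)
    for i, c in enumerate(classes):
        lut[c] = i
    t = lut[labels[labeled]]
    p = lut[prediction[labeled]]
    if (p < 0).any():
        raise ValueError("prediction contains unknown class indices")
    return np.bincount(t * k + p, minlength=k * k).reshape(k, k)


def confusion_from_matrix(matrix, classes=DEFAULT_CLASSES, sigma=DEFAULT_SIGMA):
    matrix = np.asarray(matrix, dtype=float)
    tp = np.diag(matrix)
    fp = matrix.sum(axis=0) - tp
    fn = matrix.sum(axis=1) - tp
    tn = matrix.sum() - tp - fp - fn
    return ClassConfusion(tp, fp, fn, tn, tuple(classes), sigma)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------
def _ratio(num, den):
    num, den = np.asarray(num, float), np.asarray(den, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(den == 0, np.nan, out)


def precision(conf, c=None):
    v = _ratio(conf.tp + conf.sigma, conf.tp + conf.fp + conf.sigma)
    return v if c is None else float(v[conf.index(c)])


def recall(conf, c=None):
    v = _ratio(conf.tp + conf.sigma, conf.tp + conf.fn + conf.sigma)
    return v if c is None else float(v[conf.index(c)])


def specificity(conf, c=None):
    v = _ratio(conf.tn + conf.sigma, conf.tn + conf.fp + conf.sigma)
    return v if c is None else float(v[conf.index(c)])


def dice(conf, c=None):
    v = _ratio(2 * conf.tp + conf.sigma, 2 * conf.tp + conf.fp + conf.fn + conf.sigma)
    return v if c is None else float(v[conf.index(c)])


@dataclass
class ClassMetrics:
    classes: tuple
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    dice: np.ndarray

    def macro(self):
        return {
            name: float(np.nanmean(getattr(self, name)))
            for name in ("precision", "recall", "specificity", "dice")
        }

    def to_dict(self):
        per_class = {
            int(c): {
                "precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "specificity": float(self.specificity[i]),
                "dice": float(self.dice[i]),
            }
            for i, c in enumerate(self.classes)
        }
        return {"per_class": per_class, "macro": self.macro()}


def compute_metrics(conf):
    return ClassMetrics(
        conf.classes, precision(conf), recall(conf), specificity(conf), dice(conf)
    )


@dataclass
class LossReport:
    loss: float
    metrics: ClassMetrics
    classes: tuple


def harmonic_mean_loss(conf):
    """L = 1 - 3|C| / sum_c (1/PREC + 1/RECL + 1/DICE); requires sigma > 0."""
    if conf.sigma <= 0:
        raise ValueError("harmonic_mean_loss requires sigma > 0 (training mode)")
    metrics = compute_metrics(conf)
    recips = 1.0 / metrics.precision + 1.0 / metrics.recall + 1.0 / metrics.dice
    if not np.all(np.isfinite(recips)):
        bad = [int(c) for c, r in zip(conf.classes, recips) if not np.isfinite(r)]
        raise FloatingPointError(
            f"nonfinite metric reciprocal for class(es) {bad}"
        )
    k = len(conf.classes)
    loss = 1.0 - 3.0 * k / float(recips.sum())
    return LossReport(float(np.clip(loss, 0.0, 1.0)), metrics, conf.classes)


# --------------------------------------------------------------------------
# differentiable loss on probability tensors
# --------------------------------------------------------------------------
def soft_loss(probs, labels, classes=DEFAULT_CLASSES, sigma=DEFAULT_SIGMA):
    """Differentiable harmonic-mean loss on an (N, C, H, W) probability Tensor.

    ``labels`` is an (N, H, W) sparse mask; sentinel pixels are excluded.
    Returns a scalar Tensor on the autograd graph.
    """
    if sigma <= 0:
        raise ValueError("soft_loss requires sigma > 0")
    labels = np.asarray(labels)
    _check_mask(labels, classes)
    k = len(classes)
    onehot = np.zeros(probs.shape, dtype=probs.data.dtype)
    for i, c in enumerate(classes):
        onehot[:, i][labels == c] = 1.0
    n_c = onehot.sum(axis=(0, 2, 3))  # labeled pixels per class
    labeled = (labels != SENTINEL).astype(probs.data.dtype)[:, None]
    other = labeled - onehot

    tp = (probs * onehot).sum(axis=(0, 2, 3))
    fp = (probs * other).sum(axis=(0, 2, 3))
    prec = (tp + sigma) / (tp + fp + sigma)
    recl = (tp + sigma) / (Tensor(n_c) + sigma)
    dce = (tp * 2.0 + sigma) / (tp + fp + Tensor(n_c) + sigma)
    recips = prec ** -1.0 + recl ** -1.0 + dce ** -1.0
    return 1.0 - (3.0 * k) / recips.sum()


# --------------------------------------------------------------------------
# one-vs-rest ROC / AUC
# --------------------------------------------------------------------------
@dataclass
class RocCurve:
    classes: tuple
    fpr: dict = field(default_factory=dict)
    tpr: dict = field(default_factory=dict)
    auc: dict = field(default_factory=dict)
    excluded: list = field(default_factory=list)

    @property
    def macro_auc(self):
        vals = [self.auc[c] for c in self.classes if c in self.auc]
        return float(np.mean(vals)) if vals else float("nan")


def roc_auc(probabilities, labels, classes=DEFAULT_CLASSES):
    """Per-class one-vs-rest ROC over all labeled pixels.

    probabilities: channel-last class-probability map; labels: dense or
    sparse mask.  Classes with no positive or no negative labeled pixel
    are excluded from the macro average and listed in ``excluded``.
    """
    probabilities = np.asarray(probabilities)
    labels = np.asarray(labels)
    if probabilities.shape[: labels.ndim] != labels.shape:
        raise ValueError("probability map and mask shapes differ")
    labeled = _check_mask(labels, classes)
    flat_labels = labels[labeled]
    flat_probs = probabilities[labeled]  # (n_pixels, C)
    curve = RocCurve(tuple(classes))
    for i, c in enumerate(classes):
        y = (flat_labels == c).astype(int)
        if y.sum() == 0 or y.sum() == y.size:
            curve.excluded.append(c)
            continue
        fpr, tpr, _ = _sk_roc_curve(y, flat_probs[:, i])
        curve.fpr[c], curve.tpr[c] = fpr, tpr
        curve.auc[c] = float(_sk_auc(fpr, tpr))
    return curve
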