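"""Confusion counting on sparse masks, the per-class metrics, the
harmonic-mean multiclass loss, and one-vs-rest ROC/AUC — each checked
against independent scalar oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselseg.losses import (
    ClassConfusion,
    SENTINEL,
    confusion_counts,
    confusion_from_matrix,
    confusion_matrix,
    dice,
    harmonic_mean_loss,
    precision,
    recall,
    roc_auc,
    soft_loss,
    specificity,
)
from vesselseg.nn import Tensor, softmax_channels


def make_conf(tp, fp, fn, tn, sigma=0.0, classes=(0,)):
    k = len(classes)
    arr = lambda v: np.full(k, float(v))
    return ClassConfusion(arr(tp), arr(fp), arr(fn), arr(tn), classes, sigma)


TOY_LABELS = np.array([[0, 1], [SENTINEL, 1]], dtype=np.uint8)
TOY_PREDS = np.array([[0, 1], [0, 0]], dtype=np.uint8)


class TestConfusionCounts:
    def test_all_sentinel_mask_counts_nothing(self):
        mask = np.full((4, 4), SENTINEL, dtype=np.uint8)
        conf = confusion_counts(np.zeros((4, 4), dtype=np.uint8), mask)
        for arr in (conf.tp, conf.fp, conf.fn, conf.tn):
            assert arr.sum() == 0

    def test_two_by_two_toy_by_pixel_enumeration(self):
        conf = confusion_counts(TOY_PREDS, TOY_LABELS, classes=(0, 1))
        # class 0: (0,0) hit; (1,1) labeled 1 predicted 0; (0,1) true negative
        assert (conf.tp[0], conf.fp[0], conf.fn[0], conf.tn[0]) == (1, 1, 0, 1)
        assert (conf.tp[1], conf.fp[1], conf.fn[1], conf.tn[1]) == (1, 0, 1, 1)

    def test_perfect_prediction_has_no_errors(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 6, size=(16, 16)).astype(np.uint8)
        conf = confusion_counts(labels, labels)
        assert conf.fp.sum() == 0 and conf.fn.sum() == 0

    def test_counts_partition_labeled_pixels(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 7, size=(20, 20)).astype(np.uint8)
        labels[labels == 6] = SENTINEL
        preds = rng.integers(0, 6, size=(20, 20)).astype(np.uint8)
        conf = confusion_counts(preds, labels)
        n_labeled = np.count_nonzero(labels != SENTINEL)
        totals = conf.tp + conf.fp + conf.fn + conf.tn
        assert np.all(totals == n_labeled)

    def test_sentinel_pixels_change_no_count(self):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 6, size=(10, 10)).astype(np.uint8)
        preds = rng.integers(0, 6, size=(12, 10)).astype(np.uint8)
        padded = np.vstack([labels, np.full((2, 10), SENTINEL, np.uint8)])
        a = confusion_counts(preds[:10], labels)
        b = confusion_counts(preds, padded)
        for x, y in zip((a.tp, a.fp, a.fn, a.tn), (b.tp, b.fp, b.fn, b.tn)):
            assert np.array_equal(x, y)

    def test_soft_mode_accumulates_probabilities(self):
        probs = np.zeros((1, 2, 2), dtype=float)[..., None].repeat(2, -1)
        probs[0, :, :, 0] = [[0.9, 0.2], [0.4, 0.5]]
        probs[0, :, :, 1] = 1.0 - probs[0, :, :, 0]
        labels = np.array([[[0, 1], [SENTINEL, 0]]], dtype=np.uint8)
        conf = confusion_counts(probs, labels, classes=(0, 1), mode="soft")
        assert conf.tp[0] == pytest.approx(0.9 + 0.5)
        assert conf.fp[0] == pytest.approx(0.2)
        assert conf.fn[0] == pytest.approx(0.1 + 0.5)
        assert conf.tn[0] == pytest.approx(0.8)

    def test_shape_mismatch_and_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 3), np.uint8), np.zeros((3, 2), np.uint8))
        bad = np.array([[0, 9]], dtype=np.uint8)
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((1, 2), np.uint8), bad)


class TestMetrics:
    def test_direct_arithmetic_example(self):
        conf = make_conf(8, 2, 2, 0)
        assert precision(conf, 0) == pytest.approx(0.8)
        assert recall(conf, 0) == pytest.approx(0.8)
        assert dice(conf, 0) == pytest.approx(0.8)

    def test_empty_class_with_smoothing_is_perfect(self):
        conf = make_conf(0, 0, 0, 10, sigma=1e-6)
        for metric in (precision, recall, dice):
            assert metric(conf, 0) == pytest.approx(1.0)

    def test_zero_over_zero_without_smoothing_is_undefined(self):
        conf = make_conf(0, 0, 0, 5, sigma=0.0)
        assert np.isnan(precision(conf, 0))
        assert np.isnan(dice(conf, 0))

    def test_specificity_formula(self):
        conf = make_conf(1, 3, 0, 9)
        assert specificity(conf, 0) == pytest.approx(9 / 12)

    def test_dice_is_harmonic_mean_of_precision_and_recall(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            tp, fp, fn = rng.integers(1, 50, size=3)
            conf = make_conf(tp, fp, fn, rng.integers(0, 50))
            p, r = precision(conf, 0), recall(conf, 0)
            assert dice(conf, 0) == pytest.approx(2 / (1 / p + 1 / r))


class TestHarmonicMeanLoss:
    def test_perfect_segmentation_gives_zero(self):
        conf = make_conf(50, 0, 0, 100, sigma=1e-9, classes=(0, 1, 2))
        assert harmonic_mean_loss(conf).loss == pytest.approx(0.0, abs=1e-9)

    def test_one_dead_class_drives_loss_to_one(self):
        k = 3
        tp = np.array([50.0, 50.0, 0.0])
        fpfn = np.array([0.0, 0.0, 30.0])
        conf = ClassConfusion(tp, fpfn, fpfn, np.full(k, 10.0), (0, 1, 2), 1e-9)
        assert harmonic_mean_loss(conf).loss == pytest.approx(1.0, abs=1e-6)

    def test_toy_counts_match_scalar_oracle(self):
        sigma = 1e-6
        conf = confusion_counts(TOY_PREDS, TOY_LABELS, classes=(0, 1), sigma=sigma)
        # independent scalar evaluation from the eight raw counts
        total = 0.0
        for tp, fp, fn in [(1, 1, 0), (1, 0, 1)]:
            prec = (tp + sigma) / (tp + fp + sigma)
            recl = (tp + sigma) / (tp + fn + sigma)
            dce = (2 * tp + sigma) / (2 * tp + fp + fn + sigma)
            total += 1 / prec + 1 / recl + 1 / dce
        expected = 1.0 - 3 * 2 / total
        assert harmonic_mean_loss(conf).loss == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=125, derandomize=True)
    @given(
        st.lists(
            st.tuples(*[st.integers(0, 500)] * 4), min_size=1, max_size=6
        )
    )
    def test_loss_stays_in_unit_interval(self, rows):
        k = len(rows)
        arr = np.array(rows, dtype=float)
        conf = ClassConfusion(
            arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], tuple(range(k)), 1e-6
        )
        loss = harmonic_mean_loss(conf).loss
        assert 0.0 <= loss <= 1.0

    def test_sigma_zero_rejected(self):
        with pytest.raises(ValueError):
            harmonic_mean_loss(make_conf(1, 1, 1, 1, sigma=0.0))


class TestSoftLoss:
    def test_matches_numpy_confusion_path(self):
        rng = np.random.default_rng(3)
        logits = rng.normal(size=(2, 6, 8, 8))
        labels = rng.integers(0, 7, size=(2, 8, 8)).astype(np.uint8)
        labels[labels == 6] = SENTINEL
        probs = softmax_channels(Tensor(logits))
        loss_t = soft_loss(probs, labels, sigma=1e-6)
        conf = confusion_counts(
            probs.data.transpose(0, 2, 3, 1), labels, sigma=1e-6, mode="soft"
        )
        assert loss_t.item() == pytest.approx(harmonic_mean_loss(conf).loss, rel=1e-6)

    def test_raising_correct_probability_never_raises_loss(self):
        """Finite-difference gradient sanity on the labeled pixels."""
        rng = np.random.default_rng(4)
        logits = rng.normal(size=(1, 3, 4, 4))
        labels = rng.integers(0, 3, size=(1, 4, 4)).astype(np.uint8)
        labels[0, 0, 0] = SENTINEL
        lt = Tensor(logits, requires_grad=True)
        soft_loss(softmax_channels(lt), labels, classes=(0, 1, 2)).backward()
        for y in range(4):
            for x in range(4):
                c = labels[0, y, x]
                if c == SENTINEL:
                    continue
                # pushing up the true-class logit lowers (or keeps) the loss
                assert lt.grad[0, c, y, x] <= 1e-12


class TestRocAuc:
    @staticmethod
    def pairwise_auc(scores, y):
        """Exhaustive comparison oracle: P(s+ > s-) + 0.5 P(tie)."""
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = ties = 0
        for p in pos:
            for n in neg:
                wins += p > n
                ties += p == n
        return (wins + 0.5 * ties) / (len(pos) * len(neg))

    def test_perfect_probabilities_reach_auc_one(self):
        labels = np.array([[0, 1], [2, 0]], dtype=np.uint8)
        probs = np.eye(3)[labels]
        roc = roc_auc(probs, labels, classes=(0, 1, 2))
        for c in (0, 1, 2):
            assert roc.auc[c] == 1.0
        assert roc.macro_auc == 1.0

    def test_random_scores_give_half(self):
        rng = np.random.default_rng(6)
        n = 10_000
        labels = rng.integers(0, 2, size=n).astype(np.uint8)
        p1 = rng.random(n)
        probs = np.stack([1 - p1, p1], axis=-1)
        roc = roc_auc(probs, labels, classes=(0, 1))
        assert roc.auc[1] == pytest.approx(0.5, abs=0.05)

    def test_hand_example_with_ties_matches_pairwise_oracle(self):
        scores = np.array([0.1, 0.4, 0.4, 0.8, 0.4, 0.9])
        labels = np.array([0, 0, 1, 1, 0, 1], dtype=np.uint8)
        probs = np.stack([1 - scores, scores], axis=-1)
        roc = roc_auc(probs, labels, classes=(0, 1))
        assert roc.auc[1] == pytest.approx(self.pairwise_auc(scores, labels))

    def test_small_instances_match_pairwise_oracle_exhaustively(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = rng.integers(2, 21)
            labels = rng.integers(0, 2, size=n).astype(np.uint8)
            if labels.min() == labels.max():
                continue
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            probs = np.stack([1 - scores, scores], axis=-1)
            roc = roc_auc(probs, labels, classes=(0, 1))
            assert roc.auc[1] == pytest.approx(self.pairwise_auc(scores, labels))

    def test_degenerate_class_excluded_and_reported(self):
        labels = np.array([[1, 1], [1, 1]], dtype=np.uint8)
        probs = np.zeros((2, 2, 2))
        probs[..., 1] = 1.0
        roc = roc_auc(probs, labels, classes=(0, 1))
        assert 0 in roc.excluded and 1 in roc.excluded

    def test_curve_is_monotone(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 3, size=200).astype(np.uint8)
        p = rng.dirichlet(np.ones(3), size=200)
        roc = roc_auc(p, labels, classes=(0, 1, 2))
        for c in roc.fpr:
            assert np.all(np.diff(roc.fpr[c]) >= 0)
            assert np.all(np.diff(roc.tpr[c]) >= 0)


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        labels = np.random.default_rng(9).integers(0, 6, size=(8, 8)).astype(np.uint8)
        m = confusion_matrix(labels, labels)
        assert np.array_equal(m, np.diag(m.diagonal()))

    def test_two_by_two_toy_rows(self):
        m = confusion_matrix(TOY_PREDS, TOY_LABELS, classes=(0, 1))
        assert np.array_equal(m, [[1, 0], [1, 1]])

    def test_row_sums_equal_labeled_counts_and_marginals_match(self):
        rng = np.random.default_rng(10)
        labels = rng.integers(0, 7, size=(30, 30)).astype(np.uint8)
        labels[labels == 6] = SENTINEL
        preds = rng.integers(0, 6, size=(30, 30)).astype(np.uint8)
        m = confusion_matrix(preds, labels)
        for i in range(6):
            assert m[i].sum() == np.count_nonzero(labels == i)
        conf_m = confusion_from_matrix(m)
        conf_d = confusion_counts(preds, labels)
        for a, b in zip(
            (conf_m.tp, conf_m.fp, conf_m.fn, conf_m.tn),
            (conf_d.tp, conf_d.fp, conf_d.fn, conf_d.tn),
        ):
            assert np.array_equal(a, b)
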