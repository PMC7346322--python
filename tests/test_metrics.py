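"""Region metrics, their identities, and the CE+Dice training loss."""

import numpy as np
import pytest

from modseg.autodiff import Parameter, SGD, Tensor
from modseg.metrics import (ConfusionCounts, LossConfig, REGIONS,
                            combined_loss, confusion, cross_entropy_loss,
                            dice_score, evaluate_masks, mean_foreground_dice,
                            one_hot, ppv, region_binarize, sensitivity,
                            soft_dice_loss)


def test_region_label_sets_are_the_printed_groupings():
    assert REGIONS["WT"] == {1, 2, 3, 4}
    assert REGIONS["TC"] == {1, 3, 4}
    assert REGIONS["ET"] == {4}


def test_region_binarize_set_membership():
    labels = np.array([[[0, 2], [2, 0]]])
    assert np.array_equal(region_binarize(labels, "WT"), labels == 2)
    assert not region_binarize(labels, "TC").any()
    assert not region_binarize(np.zeros((2, 2, 2), int), "WT").any()


def test_confusion_counts_direct_cases(rng):
    truth = np.zeros(100, dtype=bool)
    truth[:10] = True
    c = confusion(truth, truth)
    assert (c.tp, c.fp, c.fn, c.tn) == (10, 0, 0, 90)
    pred = np.zeros(100, dtype=bool)
    pred[10:15] = True
    truth2 = np.zeros(100, dtype=bool)
    truth2[20:25] = True
    c2 = confusion(pred, truth2)
    assert (c2.tp, c2.fp, c2.fn, c2.tn) == (0, 5, 5, 90)


def test_confusion_matches_per_voxel_loop_oracle(rng):
    pred = rng.random((16, 16, 16)) > 0.5
    truth = rng.random((16, 16, 16)) > 0.7
    c = confusion(pred, truth)
    tp = fp = fn = tn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
    assert c.total == 16 ** 3


@pytest.mark.parametrize("counts,expected", [
    ((10, 0, 0, 0), 1.0),
    ((3, 1, 1, 0), 0.75),
    ((0, 0, 0, 10), 1.0),         # empty-empty convention
])
def test_dice_formula_and_conventions(counts, expected):
    assert dice_score(ConfusionCounts(*counts)) == pytest.approx(expected)


def test_sensitivity_and_ppv_formulas():
    assert sensitivity(ConfusionCounts(8, 0, 2, 0)) == pytest.approx(0.8)
    assert ppv(ConfusionCounts(8, 2, 0, 0)) == pytest.approx(0.8)
    assert sensitivity(ConfusionCounts(0, 0, 0, 5)) == 1.0
    assert ppv(ConfusionCounts(0, 0, 0, 5)) == 1.0


def test_dice_is_harmonic_mean_of_ppv_and_sensitivity(rng):
    """Dice = 2·PPV·Sens/(PPV+Sens) over 1000 random confusion tables."""
    for _ in range(1000):
        c = ConfusionCounts(*(int(x) for x in rng.integers(0, 50, size=4)))
        s, p = sensitivity(c), ppv(c)
        if c.tp == 0:
            continue              # harmonic identity needs nonzero overlap
        assert dice_score(c) == pytest.approx(2 * p * s / (p + s))


def test_dice_symmetric_and_bounded(rng):
    for _ in range(200):
        pred = rng.random((8, 8, 8)) > rng.random()
        truth = rng.random((8, 8, 8)) > rng.random()
        d1 = dice_score(confusion(pred, truth))
        d2 = dice_score(confusion(truth, pred))
        assert d1 == pytest.approx(d2)
        assert 0.0 <= d1 <= 1.0


def test_evaluate_masks_perfect_and_degenerate():
    truth = np.zeros((6, 6, 6), dtype=np.int16)
    truth[2:4, 2:4, 2:4] = 2
    table = evaluate_masks(truth, truth)
    assert np.allclose(table.values, 1.0)
    pred = np.zeros_like(truth)
    table2 = evaluate_masks(pred, truth)
    assert table2.loc["WT", "dice"] == 0.0
    assert table2.loc["TC", "dice"] == 1.0        # label 2 not in TC


def test_evaluate_masks_hand_computed_table():
    truth = np.zeros((6, 6, 6), dtype=np.int16)
    pred = np.zeros((6, 6, 6), dtype=np.int16)
    truth[0, 0, :4] = 4                       # 4 ET voxels
    pred[0, 0, 2:6] = 4                       # overlap 2, fp 2, fn 2
    table = evaluate_masks(pred, truth)
    assert table.loc["ET", "dice"] == pytest.approx(2 * 2 / (2 * 2 + 2 + 2))
    assert table.loc["ET", "sensitivity"] == pytest.approx(0.5)
    assert table.loc["ET", "ppv"] == pytest.approx(0.5)
    # WT and TC see the same masks here (label 4 belongs to all regions)
    assert table.loc["WT", "dice"] == table.loc["ET", "dice"]


def test_mean_foreground_dice_ignores_absent_classes():
    truth = np.zeros((4, 4, 4), dtype=np.int16)
    truth[:2] = 1
    assert mean_foreground_dice(truth, truth) == 1.0
    pred = np.zeros_like(truth)
    assert mean_foreground_dice(pred, truth) == 0.0


# --- losses ---------------------------------------------------------------

def _probs_from_labels(labels, k, smooth=None):
    p = one_hot(labels, k)
    if smooth:
        p = p * (1 - smooth) + smooth / k
    return Tensor(p)


def test_soft_dice_near_zero_for_one_hot_correct():
    labels = np.zeros((4, 4, 4), dtype=np.int16)
    labels[1:3] = 1
    loss = soft_dice_loss(_probs_from_labels(labels, 2), labels,
                          LossConfig(dice_smooth=1e-5))
    assert float(loss.data) < 1e-4


def test_soft_dice_uniform_prediction_closed_form():
    """Uniform probabilities 1/K on a half-foreground grid: per-class overlap
    = (2·n_k/K + s)/(n/K + n_k + s)."""
    k = 2
    labels = np.zeros((2, 4, 4), dtype=np.int16)
    labels[1] = 1
    n = labels.size
    n1 = int((labels == 1).sum())
    probs = Tensor(np.full((1, k, 2, 4, 4), 1 / k, dtype=np.float32))
    s = 1e-5
    expected = 1 - (2 * n1 / k + s) / (n / k + n1 + s)
    loss = soft_dice_loss(probs, labels, LossConfig(dice_smooth=s))
    assert float(loss.data) == pytest.approx(expected, abs=1e-5)


def test_soft_dice_missed_class_approaches_one():
    labels = np.zeros((2, 4, 4), dtype=np.int16)
    labels[0, 0, 0] = 1
    probs = one_hot(np.zeros_like(labels), 2)
    loss = soft_dice_loss(Tensor(probs), labels, LossConfig(dice_smooth=1e-7))
    assert float(loss.data) > 0.999


def test_soft_dice_equals_one_minus_dice_on_one_hot(rng):
    """On hard one-hot predictions the soft Dice term reduces to the Dice
    metric (up to the smoothing term)."""
    labels = (rng.random((6, 6, 6)) > 0.6).astype(np.int16)
    pred = (rng.random((6, 6, 6)) > 0.6).astype(np.int16)
    loss = soft_dice_loss(_probs_from_labels(pred, 2), labels,
                          LossConfig(dice_smooth=1e-9))
    d = dice_score(confusion(pred == 1, labels == 1))
    assert float(loss.data) == pytest.approx(1 - d, abs=1e-5)


def test_cross_entropy_uniform_balanced_closed_form():
    labels = np.zeros((2, 4, 4), dtype=np.int16)
    labels[1] = 1
    probs = Tensor(np.full((1, 2, 2, 4, 4), 0.5, dtype=np.float32))
    ce = cross_entropy_loss(probs, labels)
    assert float(ce.data) == pytest.approx(np.log(2), abs=1e-5)
    total = combined_loss(probs, labels)
    dice = soft_dice_loss(probs, labels)
    assert float(total.data) == pytest.approx(
        float(ce.data) + float(dice.data), abs=1e-6)


def test_combined_loss_near_zero_when_perfect():
    labels = np.zeros((4, 4, 4), dtype=np.int16)
    labels[2:] = 1
    loss = combined_loss(_probs_from_labels(labels, 2), labels)
    assert float(loss.data) <= 1e-3


def test_combined_loss_decreases_under_gradient_descent(rng):
    """50 SGD steps on logits of a fixed 16³ toy batch reduce the loss."""
    labels = (rng.random((16, 16, 16)) > 0.7).astype(np.int16)
    logits = Parameter(rng.normal(size=(1, 2, 16, 16, 16)).astype(np.float32))
    opt = SGD([logits], lr=100.0, momentum=0.9)   # per-voxel grads are ~1/n
    losses = []
    for _ in range(50):
        probs = logits.softmax(axis=1)
        loss = combined_loss(probs, labels)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(float(loss.data))
    assert losses[-1] < losses[0] * 0.5
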