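"""Metrics, threshold selection, and confidence intervals vs oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ltpdetect.evaluate import (
    ConfusionCounts,
    auc_ci,
    confusion_at_threshold,
    evaluate_predictions,
    metrics_from_confusion,
    pr_curve,
    proportion_ci,
    roc_auc,
    select_threshold,
)


# ---------------------------------------------------------------------------
# confusion counts


def test_basic_confusion():
    c = confusion_at_threshold([0.9, 0.2], [1, 0], 0.5)
    assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 0, 0)


def test_threshold_zero_predicts_all_positive():
    c = confusion_at_threshold([0.3, 0.6, 0.1], [1, 0, 0], 0.0)
    assert c.fn == 0 and c.tn == 0
    assert c.tp == 1 and c.fp == 2


def test_probability_equal_to_threshold_is_positive():
    c = confusion_at_threshold([0.5], [1], 0.5)
    assert c.tp == 1 and c.fn == 0


def test_empty_input_rejected():
    with pytest.raises(ValueError, match="empty"):
        confusion_at_threshold([], [], 0.5)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


# ---------------------------------------------------------------------------
# metric formulas


def test_perfect_counts_give_all_ones():
    rep = metrics_from_confusion(ConfusionCounts(tp=1, fp=0, tn=1, fn=0))
    assert rep.sensitivity == rep.specificity == rep.ppv == rep.accuracy == 1.0


def test_reference_confusion_reproduces_printed_metrics():
    """tp=155, fp=15, tn=625, fn=5 on 160/640 patches."""
    rep = metrics_from_confusion(ConfusionCounts(tp=155, fp=15, tn=625, fn=5))
    assert round(100 * rep.sensitivity, 2) == 96.88
    assert round(100 * rep.specificity, 2) == 97.66  # 625/640 = 97.65625
    assert round(100 * rep.ppv, 2) == 91.18          # 155/170
    assert rep.accuracy == (155 + 625) / 800 == 0.975


def test_zero_denominator_flagged_not_nan():
    rep = metrics_from_confusion(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
    assert rep.ppv is None
    assert "ppv" in rep.undefined
    assert rep.specificity == 1.0


# ---------------------------------------------------------------------------
# ROC / PR


def pair_count_auc(probs, labels):
    """Exhaustive positive-negative pair counting (ties count half)."""
    probs = np.asarray(probs, float)
    labels = np.asarray(labels, int)
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfect_separation():
    probs = [0.9, 0.8, 0.2, 0.1]
    labels = [1, 1, 0, 0]
    assert roc_auc(probs, labels) == 1.0
    assert pr_curve(probs, labels)[-1] == 1.0


def test_alternating_example_auc():
    probs = [0.9, 0.8, 0.7, 0.6]
    labels = [1, 0, 1, 0]
    assert pair_count_auc(probs, labels) == 0.75
    assert roc_auc(probs, labels) == 0.75


def test_uninformative_probs_give_half_auc():
    rng = np.random.default_rng(0)
    probs = rng.random(4000)
    labels = rng.integers(0, 2, 4000)
    assert abs(roc_auc(probs, labels) - 0.5) < 0.03


def test_auc_matches_pair_counting_oracle_on_random_inputs():
    rng = np.random.default_rng(7)
    for trial in range(20):
        n = int(rng.integers(5, 200))
        probs = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            continue
        assert roc_auc(probs, labels) == pytest.approx(
            pair_count_auc(probs, labels), abs=1e-12
        )


def test_average_precision_is_step_sum():
    probs = np.array([0.9, 0.7, 0.6, 0.4])
    labels = np.array([1, 0, 1, 0])
    # manual non-interpolated sum over recall increments
    order = np.argsort(-probs)
    y = labels[order]
    tp = np.cumsum(y)
    precision = tp / np.arange(1, len(y) + 1)
    recall = tp / y.sum()
    ap_manual = np.sum(np.diff(np.concatenate([[0], recall])) * precision)
    assert pr_curve(probs, labels)[-1] == pytest.approx(ap_manual, abs=1e-12)


def test_single_class_rejected():
    with pytest.raises(ValueError, match="class"):
        roc_auc([0.1, 0.9], [1, 1])
    with pytest.raises(ValueError, match="class"):
        select_threshold([0.1, 0.9], [0, 0])


# ---------------------------------------------------------------------------
# threshold selection


def brute_force_threshold(probs, labels):
    """Oracle: evaluate every candidate cut the selector considers."""
    distinct = np.unique(probs)
    cands = ([distinct[0]] + list((distinct[:-1] + distinct[1:]) / 2)
             + [min(1.0, (distinct[-1] + 1) / 2)])
    best = None
    for t in cands:
        c = confusion_at_threshold(probs, labels, t)
        key = ((c.tp / c.positives + c.tn / c.negatives) / 2,
               c.tn / c.negatives, t)
        if best is None or key > best[0]:
            best = (key, t)
    return best[1]


def test_separable_validation_returns_gap_midpoint():
    probs = [0.9, 0.8, 0.2, 0.1]
    labels = [1, 1, 0, 0]
    assert select_threshold(probs, labels) == pytest.approx(0.5)


def test_documented_example_lands_in_expected_interval():
    probs = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
    labels = [1, 1, 1, 0, 0, 0]
    t = select_threshold(probs, labels)
    assert 0.7 < t <= 0.8
    # balanced accuracy at t: sens 2/3, spec 1
    c = confusion_at_threshold(probs, labels, t)
    assert c.tn == 3 and c.tp == 2


def test_degenerate_identical_probs_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        t = select_threshold([0.4, 0.4, 0.4], [1, 0, 1])
    assert t == 0.4


@settings(max_examples=100, derandomize=True)
@given(st.integers(0, 10_000))
def test_selector_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 40))
    probs = np.round(rng.random(n), 1)
    labels = rng.integers(0, 2, n)
    if len(np.unique(labels)) < 2 or len(np.unique(probs)) < 2:
        return
    assert select_threshold(probs, labels) == brute_force_threshold(
        probs, labels
    )


# ---------------------------------------------------------------------------
# confidence intervals


def test_proportion_ci_boundaries():
    lo, hi = proportion_ci(10, 10)
    assert hi == 1.0 and 0 < lo < 1
    lo, hi = proportion_ci(0, 10)
    assert lo == 0.0 and 0 < hi < 1
    with pytest.raises(ValueError):
        proportion_ci(11, 10)


def test_proportion_ci_matches_exact_binomial():
    statsmodels = pytest.importorskip("statsmodels.stats.proportion")
    lo, hi = proportion_ci(155, 160)
    ref_lo, ref_hi = statsmodels.proportion_confint(155, 160, method="beta")
    assert lo == pytest.approx(ref_lo, abs=1e-10)
    assert hi == pytest.approx(ref_hi, abs=1e-10)


def test_auc_ci_contains_auc_and_tightens_with_n():
    rng = np.random.default_rng(4)
    for n in (40, 400):
        pos = rng.normal(1.0, 1.0, n)
        neg = rng.normal(0.0, 1.0, n)
        probs = 1 / (1 + np.exp(-np.concatenate([pos, neg])))
        labels = np.r_[np.ones(n), np.zeros(n)]
        lo, hi = auc_ci(probs, labels)
        auc = roc_auc(probs, labels)
        assert lo <= auc <= hi
        if n == 40:
            wide = hi - lo
    assert (hi - lo) < wide


def test_delong_variance_against_direct_placements():
    """The fast placement computation equals the O(mn) double loop."""
    from ltpdetect.evaluate import _delong_variance

    rng = np.random.default_rng(9)
    probs = np.round(rng.random(60), 2)
    labels = rng.integers(0, 2, 60)
    pos, neg = probs[labels == 1], probs[labels == 0]
    v10 = np.array([np.mean((p > neg) + 0.5 * (p == neg)) for p in pos])
    v01 = np.array([np.mean((pos > q) + 0.5 * (pos == q)) for q in neg])
    auc_ref = v10.mean()
    var_ref = np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)
    auc, var = _delong_variance(probs, labels)
    assert auc == pytest.approx(auc_ref, abs=1e-12)
    assert var == pytest.approx(var_ref, abs=1e-12)


def test_full_report_assembles_all_metrics():
    rng = np.random.default_rng(2)
    probs = np.r_[rng.uniform(0.6, 1, 50), rng.uniform(0, 0.5, 150)]
    labels = np.r_[np.ones(50), np.zeros(150)]
    rep = evaluate_predictions(probs, labels, threshold=0.55)
    assert rep.sensitivity == 1.0 and rep.specificity == 1.0
    assert rep.auc == 1.0 and rep.average_precision == 1.0
    for key in ("sensitivity", "specificity", "ppv", "accuracy", "auc"):
        lo, hi = rep.confidence_intervals[key]
        assert 0.0 <= lo <= hi <= 1.0
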