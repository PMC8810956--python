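"""Classification metrics, operating-point selection, and curves.

The operating threshold is chosen on the validation split as the cut
maximizing balanced accuracy, i.e. the mean of sensitivity and
specificity (equivalent to maximizing the Youden index); predictions are
positive when probability ≥ threshold.  Confidence intervals use the
Clopper–Pearson exact interval for proportions and DeLong's method for
the AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn import metrics as _skm

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_at_threshold",
    "metrics_from_confusion",
    "roc_auc",
    "roc_curve",
    "pr_curve",
    "select_threshold",
    "proportion_ci",
    "auc_ci",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.positives + self.negatives


@dataclass
class MetricsReport:
    """Proportion metrics (with any undefined ones flagged) plus curve areas."""

    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    accuracy: float | None = None
    auc: float | None = None
    average_precision: float | None = None
    threshold: float | None = None
    confidence_intervals: dict[str, tuple[float, float]] = field(default_factory=dict)
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "ppv": self.ppv, "accuracy": self.accuracy, "auc": self.auc,
            "average_precision": self.average_precision,
            "threshold": self.threshold,
        }


def _check_probs_labels(probs, labels, require_both_classes=False):
    probs = np.asarray(probs, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if probs.size == 0:
        raise ValueError("empty input")
    if probs.shape != labels.shape:
        raise ValueError("probabilities and labels differ in length")
    if require_both_classes and len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return probs, labels


def confusion_at_threshold(probs, labels, threshold: float) -> ConfusionCounts:
    """Confusion counts with the rule: positive iff probability ≥ threshold."""
    probs, labels = _check_probs_labels(probs, labels)
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)), fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)), fn=int(np.sum(~pred & pos)),
    )


def metrics_from_confusion(c: ConfusionCounts) -> MetricsReport:
    """Sensitivity, specificity, PPV and accuracy from confusion counts.

    A metric with a zero denominator is left ``None`` and listed in
    ``report.undefined`` rather than silently propagating NaN.
    """
    report = MetricsReport()
    pairs = {
        "sensitivity": (c.tp, c.positives),
        "specificity": (c.tn, c.negatives),
        "ppv": (c.tp, c.tp + c.fp),
        "accuracy": (c.tp + c.tn, c.total),
    }
    for name, (num, den) in pairs.items():
        if den == 0:
            report.undefined.append(name)
        else:
            setattr(report, name, num / den)
    return report


def roc_auc(probs, labels) -> float:
    """Area under the ROC curve (equals the Mann–Whitney rank statistic)."""
    probs, labels = _check_probs_labels(probs, labels, require_both_classes=True)
    return float(_skm.roc_auc_score(labels, probs))


def roc_curve(probs, labels):
    probs, labels = _check_probs_labels(probs, labels, require_both_classes=True)
    fpr, tpr, thr = _skm.roc_curve(labels, probs)
    return fpr, tpr, thr


def pr_curve(probs, labels):
    """Precision–recall curve and its step-summed area (average precision).

    Returns ``(precision, recall, thresholds, average_precision)``; AP is
    the non-interpolated sum ``Σ (R_i − R_{i−1}) · P_i``.
    """
    probs, labels = _check_probs_labels(probs, labels, require_both_classes=True)
    precision, recall, thr = _skm.precision_recall_curve(labels, probs)
    ap = float(_skm.average_precision_score(labels, probs))
    return precision, recall, thr, ap


def select_threshold(probs_val, labels_val) -> float:
    """Operating threshold maximizing (sensitivity + specificity)/2.

    Candidate cuts are the midpoints between consecutive distinct
    validation probabilities plus the two boundary cuts (everything
    positive / everything negative).  Ties prefer the cut with the higher
    specificity, then the larger threshold.  A single distinct probability
    is degenerate: that value is returned with a warning.
    """
    probs, labels = _check_probs_labels(probs_val, labels_val,
                                        require_both_classes=True)
    distinct = np.unique(probs)
    if distinct.size == 1:
        warnings.warn("all validation probabilities identical; threshold is "
                      "degenerate", stacklevel=2)
        return float(distinct[0])
    candidates = [distinct[0]]  # everything predicted positive
    candidates += list((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append(min(1.0, (distinct[-1] + 1.0) / 2.0))  # everything negative
    best = None
    for t in candidates:
        c = confusion_at_threshold(probs, labels, t)
        sens = c.tp / c.positives
        spec = c.tn / c.negatives
        key = ((sens + spec) / 2.0, spec, t)
        if best is None or key > best[0]:
            best = (key, t)
    return float(best[1])


def proportion_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact (beta-quantile) interval for k successes of n."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    alpha = 1.0 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


def _delong_variance(probs, labels):
    """DeLong placement-value variance of the empirical AUC."""
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    m, n = len(pos), len(neg)

    def placements(a, b):
        # for each a_i: fraction of b below it, counting ties as half
        order = np.argsort(b)
        bs = b[order]
        lo = np.searchsorted(bs, a, side="left")
        hi = np.searchsorted(bs, a, side="right")
        return (lo + 0.5 * (hi - lo)) / len(b)

    v10 = placements(pos, neg)          # P(neg < pos_i)
    v01 = 1.0 - placements(neg, pos)    # P(neg_j < pos)
    auc = float(np.mean(v10))
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    return auc, var


def auc_ci(probs, labels, level: float = 0.95) -> tuple[float, float]:
    """DeLong Wald interval for the AUC, clipped to [0, 1]."""
    probs, labels = _check_probs_labels(probs, labels, require_both_classes=True)
    auc, var = _delong_variance(probs, labels)
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return max(0.0, auc - half), min(1.0, auc + half)


def evaluate_predictions(probs, labels, threshold: float,
                         level: float = 0.95) -> MetricsReport:
    """Full report at an operating threshold: proportions, AUC, AP, CIs."""
    probs, labels = _check_probs_labels(probs, labels, require_both_classes=True)
    c = confusion_at_threshold(probs, labels, threshold)
    report = metrics_from_confusion(c)
    report.threshold = float(threshold)
    report.auc = roc_auc(probs, labels)
    *_, report.average_precision = pr_curve(probs, labels)
    cis = {
        "sensitivity": (c.tp, c.positives),
        "specificity": (c.tn, c.negatives),
        "ppv": (c.tp, c.tp + c.fp),
        "accuracy": (c.tp + c.tn, c.total),
    }
    for name, (k, n) in cis.items():
        if n > 0:
            report.confidence_intervals[name] = proportion_ci(k, n, level)
    report.confidence_intervals["auc"] = auc_ci(probs, labels, level)
    return report


def metrics_table(report: MetricsReport) -> "pd.DataFrame":  # noqa: F821
    """Tabular (CSV-ready) view of a metrics report, percentages included."""
    import pandas as pd

    rows = []
    for name, value in report.as_dict().items():
        if value is None:
            continue
        lo_hi = report.confidence_intervals.get(name)
        rows.append({
            "metric": name, "value": value,
            "ci_low": lo_hi[0] if lo_hi else np.nan,
            "ci_high": lo_hi[1] if lo_hi else np.nan,
        })
    return pd.DataFrame(rows)


def plot_curves(probs, labels, path_roc=None, path_pr=None):
    """Write ROC and PR curve plots (PNG) and return the figure objects."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fpr, tpr, _ = roc_curve(probs, labels)
    precision, recall, _, ap = pr_curve(probs, labels)
    auc = roc_auc(probs, labels)

    fig_roc, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, lw=1.5, label=f"AUC = {auc:.3f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.7)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    if path_roc:
        fig_roc.savefig(path_roc, dpi=120, bbox_inches="tight")

    fig_pr, ax = plt.subplots(figsize=(4, 4))
    ax.plot(recall, precision, lw=1.5, drawstyle="steps-post",
            label=f"AP = {ap:.3f}")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.legend(loc="lower left")
    if path_pr:
        fig_pr.savefig(path_pr, dpi=120, bbox_inches="tight")
    return fig_roc, fig_pr
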