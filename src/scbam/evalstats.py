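"""Evaluation metrics and inference for finger-decoding reports.

Accuracy and Cohen's kappa are computed from confusion counts by their
closed forms; significance of a single decoder is assessed with a
trial-level label-permutation test, model comparisons with a paired
t-test over the ten finger-pair accuracies, and across-subject stability
with a non-parametric bootstrap of the mean accuracy. ROC points for the
binary classifiers come from a threshold sweep over the positive-class
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _scipy_stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .exceptions import InvalidArgumentError, UndefinedStatisticError

__all__ = [
    "ConfusionMatrix",
    "confusion_matrix",
    "accuracy",
    "cohens_kappa",
    "permutation_test",
    "paired_ttest",
    "bootstrap_ci",
    "roc_points",
]


@dataclass
class ConfusionMatrix:
    """K x K confusion counts; rows are truth, columns are prediction."""

    counts: np.ndarray
    class_labels: list

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise InvalidArgumentError("confusion matrix must be square")
        if len(self.class_labels) != self.counts.shape[0]:
            raise InvalidArgumentError("class_labels must match matrix size")
        if np.any(self.counts < 0):
            raise InvalidArgumentError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_matrix(true_labels, predicted_labels, class_labels=None) -> ConfusionMatrix:
    """Tally a confusion matrix from aligned truth/prediction vectors."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise InvalidArgumentError("label vectors must have equal length")
    if class_labels is None:
        class_labels = sorted(set(t.tolist()) | set(p.tolist()))
    index = {c: i for i, c in enumerate(class_labels)}
    counts = np.zeros((len(class_labels), len(class_labels)), dtype=int)
    for ti, pi in zip(t.tolist(), p.tolist()):
        counts[index[ti], index[pi]] += 1
    return ConfusionMatrix(counts, list(class_labels))


def accuracy(cm: ConfusionMatrix) -> float:
    """Fraction of correctly classified trials, trace(cm) / total.

    For the binary case this is (TP + TN) / (TP + TN + FP + FN).
    """
    if cm.total == 0:
        raise InvalidArgumentError("empty confusion matrix")
    return float(np.trace(cm.counts) / cm.total)


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement kappa = (P_o - P_e) / (1 - P_e).

    P_o is the observed agreement trace/total; P_e the agreement expected
    from the row and column margins alone.
    """
    n = cm.total
    if n == 0:
        raise InvalidArgumentError("empty confusion matrix")
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1)
    col = cm.counts.sum(axis=0)
    p_e = float(np.dot(row, col)) / (n * n)
    if p_e == 1.0:
        raise UndefinedStatisticError("kappa undefined: expected agreement is 1")
    return float((p_o - p_e) / (1.0 - p_e))


def permutation_test(true_labels, predicted_labels, n_perm: int = 5000, rng=None):
    """Trial-level label-permutation test of decoding accuracy.

    Predictions are held fixed while the true-label vector is shuffled
    ``n_perm`` times; the shuffled accuracy of each permutation forms the
    empirical null. Returns a dict with the observed accuracy, the
    add-one-smoothed p-value ``(1 + #{acc_perm >= acc_obs}) / (n_perm + 1)``,
    the unsmoothed proportion ``p_raw``, and the null mean accuracy.
    """
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise InvalidArgumentError("label vectors must have equal length")
    if n_perm < 1:
        raise InvalidArgumentError("n_perm must be >= 1")
    rng = np.random.default_rng(rng)
    acc_obs = float(np.mean(t == p))
    n = t.size
    # one vectorized pass: rows are independent shuffles of the truth
    perm_acc = np.empty(n_perm)
    shuffled = t.copy()
    for i in range(n_perm):
        rng.shuffle(shuffled)
        perm_acc[i] = np.count_nonzero(shuffled == p) / n
    n_ge = int(np.count_nonzero(perm_acc >= acc_obs))
    return {
        "acc_observed": acc_obs,
        "p_value": (1 + n_ge) / (n_perm + 1),
        "p_raw": n_ge / n_perm,
        "null_mean": float(perm_acc.mean()),
        "null_quantiles": {
            "q025": float(np.quantile(perm_acc, 0.025)),
            "q975": float(np.quantile(perm_acc, 0.975)),
        },
        "n_perm": n_perm,
    }


_STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in _STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


def paired_ttest(acc_a, acc_b):
    """Two-sided paired t-test between two models' per-pair accuracies.

    Returns (t, p, stars) with stars at the 0.05 / 0.01 / 0.001 levels.
    Raises :class:`UndefinedStatisticError` when the paired differences
    have zero variance (t is undefined).
    """
    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise InvalidArgumentError("need two aligned vectors of length >= 2")
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        raise UndefinedStatisticError("paired differences have zero variance")
    t, p = _scipy_stats.ttest_rel(a, b)
    return float(t), float(p), significance_stars(float(p))


def bootstrap_ci(subject_accuracies, n_boot: int = 1000, level: float = 0.95, rng=None):
    """Percentile bootstrap CI for the across-subject mean accuracy."""
    x = np.asarray(subject_accuracies, dtype=float)
    if x.size < 2:
        raise InvalidArgumentError("need at least 2 subject accuracies")
    if not 0 < level < 1:
        raise InvalidArgumentError("level must be in (0, 1)")
    rng = np.random.default_rng(rng)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return float(np.quantile(means, alpha)), float(np.quantile(means, 1.0 - alpha))


def roc_points(scores, labels, positive_label=None):
    """ROC curve of a binary classifier from positive-class probabilities.

    Returns (points, auc) where points is a list of (FPR, TPR) pairs from
    a sweep over the unique score thresholds.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise InvalidArgumentError("scores and labels must align")
    classes = sorted(set(y.tolist()))
    if len(classes) != 2:
        raise InvalidArgumentError("labels must contain exactly two classes")
    if positive_label is None:
        positive_label = classes[1]
    fpr, tpr, _ = _sk_roc_curve(y, s, pos_label=positive_label)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_sk_auc(fpr, tpr))
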