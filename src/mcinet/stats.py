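"""Evaluation statistics for out-of-fold predictions.

Point metrics (accuracy, sensitivity, specificity, balanced accuracy
BAC = (SEN + SPE) / 2), exact Clopper-Pearson binomial confidence
intervals, ROC/AUC with DeLong variance-based intervals, and McNemar
comparisons between paired classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.proportion import proportion_confint


@dataclass
class ClassificationReport:
    """Confusion counts, rates and confidence intervals for one evaluation."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float | None
    spe: float | None
    bac: float | None
    auc: float | None = None
    ci_acc: tuple[float, float] | None = None
    ci_sen: tuple[float, float] | None = None
    ci_spe: tuple[float, float] | None = None
    ci_auc: tuple[float, float] | None = None
    roc: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        out = {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "acc": self.acc, "sen": self.sen, "spe": self.spe, "bac": self.bac,
            "auc": self.auc,
        }
        for name in ("ci_acc", "ci_sen", "ci_spe", "ci_auc"):
            ci = getattr(self, name)
            out[name] = None if ci is None else [float(ci[0]), float(ci[1])]
        return out


def confusion_metrics(y_true, y_pred, positive) -> ClassificationReport:
    """Counts and rates with ``positive`` as the disease-progression class.

    A rate whose denominator is empty (no positive or no negative subjects)
    is reported as ``None`` rather than 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    pos = y_true == positive
    pred_pos = y_pred == positive
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sen = tp / (tp + fn) if tp + fn else None
    spe = tn / (tn + fp) if tn + fp else None
    bac = (sen + spe) / 2 if sen is not None and spe is not None else None
    return ClassificationReport(tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, sen=sen, spe=spe, bac=bac)


def clopper_pearson(successes: int, trials: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (beta-quantile) binomial confidence interval."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("require 0 <= successes <= trials, trials >= 1")
    lo, hi = proportion_confint(successes, trials, alpha=1.0 - level, method="beta")
    # statsmodels returns NaN at the boundary cases; the exact limits are 0/1
    lo = 0.0 if successes == 0 or np.isnan(lo) else float(lo)
    hi = 1.0 if successes == trials or np.isnan(hi) else float(hi)
    return lo, hi


def roc_auc(scores, y_true, positive) -> tuple[np.ndarray, float]:
    """ROC polyline and AUC (Mann-Whitney concordance, ties counted 1/2)."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    y = (y_true == positive).astype(int)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, scores)
    auc = float(roc_auc_score(y, scores))
    return np.column_stack([fpr, tpr]), auc


def _delong_components(scores, y) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and its DeLong structural components (placement values)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    # V10[i]: fraction of negatives scored below positive i (ties 1/2)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / neg.size for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / pos.size for q in neg])
    return float(v10.mean()), v10, v01


def delong_variance(scores, y_true, positive) -> tuple[float, float]:
    """AUC point estimate and its DeLong variance."""
    y = (np.asarray(y_true) == positive).astype(int)
    scores = np.asarray(scores, dtype=float)
    if np.sum(y == 1) < 2 or np.sum(y == 0) < 2:
        raise ValueError("need at least 2 subjects per class")
    auc, v10, v01 = _delong_components(scores, y)
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    return auc, float(var)


def delong_ci(scores, y_true, positive, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation AUC interval from the DeLong variance.

    With perfect separation the variance degenerates to zero and the
    interval collapses onto the point estimate.
    """
    auc, var = delong_variance(scores, y_true, positive)
    z = sps.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def delong_paired_test(scores_a, scores_b, y_true, positive) -> tuple[float, float]:
    """Two-sided DeLong test for equal AUC of two paired score sets.

    Returns ``(auc_a - auc_b, p_value)``.  Used for the per-K significance
    comparisons between feature-selection algorithms.
    """
    y = (np.asarray(y_true) == positive).astype(int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    auc_a, v10a, v01a = _delong_components(a, y)
    auc_b, v10b, v01b = _delong_components(b, y)
    m, n = v10a.size, v01a.size
    var = (
        np.cov(v10a, v10b)[0, 0] + np.cov(v10a, v10b)[1, 1] - 2 * np.cov(v10a, v10b)[0, 1]
    ) / m + (
        np.cov(v01a, v01b)[0, 0] + np.cov(v01a, v01b)[1, 1] - 2 * np.cov(v01a, v01b)[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        return diff, 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return diff, float(2.0 * sps.norm.sf(abs(z)))


def mcnemar_test(pred_a, pred_b, y_true, exact: bool = True) -> float:
    """Two-sided McNemar test on paired correct/incorrect outcomes.

    ``b`` counts subjects only classifier A gets right, ``c`` those only B
    gets right.  The exact version is an exact binomial test on the
    discordant pairs (appropriate for the small fold counts here); the
    chi-square version applies the continuity correction.
    """
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    y_true = np.asarray(y_true)
    if not (pred_a.shape == pred_b.shape == y_true.shape):
        raise ValueError("all inputs must have equal length")
    correct_a = pred_a == y_true
    correct_b = pred_b == y_true
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    if b + c == 0:
        return 1.0
    if exact:
        return float(sps.binomtest(min(b, c), b + c, 0.5, alternative="two-sided").pvalue)
    chi2 = (abs(b - c) - 1.0) ** 2 / (b + c)
    return float(sps.chi2.sf(chi2, df=1))


def full_report(
    y_true, y_pred, scores, positive, level: float = 0.95
) -> ClassificationReport:
    """Confusion metrics plus Clopper-Pearson and DeLong intervals."""
    report = confusion_metrics(y_true, y_pred, positive)
    report.ci_acc = clopper_pearson(report.tp + report.tn, report.n, level)
    if report.sen is not None:
        report.ci_sen = clopper_pearson(report.tp, report.tp + report.fn, level)
    if report.spe is not None:
        report.ci_spe = clopper_pearson(report.tn, report.tn + report.fp, level)
    if scores is not None:
        roc, auc = roc_auc(scores, y_true, positive)
        report.roc = roc
        report.auc = auc
        try:
            report.ci_auc = delong_ci(scores, y_true, positive, level)
        except ValueError:
            report.ci_auc = None
    return report
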