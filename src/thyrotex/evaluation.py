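"""Classifier evaluation: error rates, exact binomial CIs, ROC/AUC,
and the two-sample comparison of pooled ADC values.

Sensitivity/specificity intervals use the Clopper-Pearson exact
binomial construction; the AUC interval uses the Hanley-McNeil standard
error.  The group comparison is a Welch (unequal-variance) t test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    ci95: tuple[float, float]


def misclassification_rate(correct: int, total: int) -> float:
    """Percentage of misclassified units, 100 * (1 - correct/total)."""
    if total <= 0:
        raise ValueError("total must be > 0")
    if not 0 <= correct <= total:
        raise ValueError("need 0 <= correct <= total")
    return 100.0 * (1.0 - correct / total)


def clopper_pearson(x: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI for a proportion, as proportions in [0, 1]."""
    if n <= 0:
        raise ValueError("n must be > 0")
    alpha = 1.0 - conf
    lo = 0.0 if x == 0 else float(sps.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(sps.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def sens_spec_ci(counts: ConfusionCounts) -> dict:
    """Sensitivity and specificity with exact 95% CIs (all in percent)."""
    out = {}
    if counts.tp + counts.fn > 0:
        sens = counts.tp / (counts.tp + counts.fn)
        lo, hi = clopper_pearson(counts.tp, counts.tp + counts.fn)
        out["sensitivity"] = 100 * sens
        out["sensitivity_ci95"] = (100 * lo, 100 * hi)
    if counts.tn + counts.fp > 0:
        spec = counts.tn / (counts.tn + counts.fp)
        lo, hi = clopper_pearson(counts.tn, counts.tn + counts.fp)
        out["specificity"] = 100 * spec
        out["specificity_ci95"] = (100 * lo, 100 * hi)
    if not out:
        raise ValueError("both classes empty")
    return out


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve by threshold sweep with trapezoidal AUC.

    Tied scores step simultaneously.  The 95% CI uses the Hanley-McNeil
    standard error, clipped to [0, 1].
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    # cumulative counts at each distinct threshold (descending scores)
    distinct = np.r_[np.nonzero(np.diff(s))[0], len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc = float(np.trapezoid(tpr, fpr))

    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se2 = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2)
           + (n_neg - 1) * (q2 - auc**2)) / (n_pos * n_neg)
    se = np.sqrt(max(se2, 0.0))
    lo = float(np.clip(auc - 1.959963984540054 * se, 0, 1))
    hi = float(np.clip(auc + 1.959963984540054 * se, 0, 1))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds,
                    auc=auc, ci95=(lo, hi))


def welch_t_test(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float, float]:
    """Welch unequal-variance t test: returns (t, df, two-sided p).

    Two degenerate equal groups (zero variance, equal means) give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return float("inf"), float(len(a) + len(b) - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)
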