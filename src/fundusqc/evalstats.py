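"""Evaluation statistics: sensitivity/specificity/accuracy with Wilson CIs,
ROC AUC with a DeLong-variance interval, the paired DeLong test, the pooled
two-proportion z-test and the independent two-sample t-test.

Conventions: two-sided tests throughout; AUC ties get half credit
(Mann-Whitney); proportion intervals are Wilson score by default with
Clopper-Pearson available via a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .synthetic import ValidationError


@dataclass
class MetricWithCI:
    estimate: float | None
    ci_low: float | None
    ci_high: float | None

    def as_tuple(self):
        return self.estimate, self.ci_low, self.ci_high


@dataclass
class BinaryEvalResult:
    sensitivity: MetricWithCI
    specificity: MetricWithCI
    accuracy: MetricWithCI
    n_pos: int
    n_neg: int
    auc: MetricWithCI | None = None


def _proportion_ci(x: int, n: int, alpha: float = 0.05,
                   method: str = "wilson") -> MetricWithCI:
    if n == 0:
        return MetricWithCI(None, None, None)
    meth = {"wilson": "wilson", "clopper-pearson": "beta"}[method]
    low, high = proportion_confint(x, n, alpha=alpha, method=meth)
    return MetricWithCI(x / n, float(low), float(high))


def binary_metrics(labels, calls, alpha: float = 0.05,
                   ci_method: str = "wilson") -> BinaryEvalResult:
    """Sensitivity, specificity and accuracy with score CIs.

    A metric whose denominator is empty (e.g. sensitivity with no positive
    labels) is reported as missing rather than raising.
    """
    labels = np.asarray(labels).astype(int)
    calls = np.asarray(calls).astype(int)
    if labels.shape != calls.shape or labels.ndim != 1 or labels.size == 0:
        raise ValidationError("labels and calls must be equal-length 1-D arrays")
    if not set(np.unique(labels)) <= {0, 1} or not set(np.unique(calls)) <= {0, 1}:
        raise ValidationError("labels and calls must be binary 0/1")
    tp = int(((labels == 1) & (calls == 1)).sum())
    tn = int(((labels == 0) & (calls == 0)).sum())
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    return BinaryEvalResult(
        sensitivity=_proportion_ci(tp, n_pos, alpha, ci_method),
        specificity=_proportion_ci(tn, n_neg, alpha, ci_method),
        accuracy=_proportion_ci(tp + tn, labels.size, alpha, ci_method),
        n_pos=n_pos, n_neg=n_neg,
    )


# -- DeLong machinery ------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative);
    their means equal the Mann-Whitney AUC with half-credit ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValidationError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return v10, v01


def roc_auc(scores, labels, alpha: float = 0.05) -> MetricWithCI:
    """AUC via the Mann-Whitney statistic with a DeLong-variance CI,
    clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    v10, v01 = _delong_components(scores, labels)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / v10.size + v01.var(ddof=1) / v01.size
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return MetricWithCI(auc, float(np.clip(auc - half, 0, 1)),
                        float(np.clip(auc + half, 0, 1)))


def delong_test(scores_1, scores_2, labels) -> tuple[float, float, float]:
    """Paired DeLong comparison of two correlated AUCs on the same labels.

    Returns (auc_1, auc_2, two-sided p). A degenerate variance of the AUC
    difference yields p = 1 with a warning.
    """
    scores_1 = np.asarray(scores_1, dtype=float)
    scores_2 = np.asarray(scores_2, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores_1.shape != scores_2.shape or scores_1.shape != labels.shape:
        raise ValidationError("paired scores and labels must be equal length")
    v10_1, v01_1 = _delong_components(scores_1, labels)
    v10_2, v01_2 = _delong_components(scores_2, labels)
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.stack([v10_1, v10_2]))
    s01 = np.cov(np.stack([v01_1, v01_2]))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0 or not np.isfinite(var_diff):
        warnings.warn("degenerate variance in DeLong test; p set to 1")
        return auc1, auc2, 1.0
    z = (auc1 - auc2) / np.sqrt(var_diff)
    p = 2 * sps.norm.sf(abs(z))
    return auc1, auc2, float(p)


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-sided z-test for two proportions; returns (z, p).

    A pooled proportion of exactly 0 or 1 carries no evidence against
    equality, so p is reported as 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValidationError("need 0 <= x <= n with n > 0")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return float(z), float(2 * sps.norm.sf(abs(z)))


def two_sample_t(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Independent two-sample t-test; returns (t, two-sided p).

    Equal-variance (pooled) by default, Welch via ``equal_var=False``.
    Two zero-variance samples are rejected (the statistic is undefined).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValidationError("zero variance in both samples; t undefined")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)
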