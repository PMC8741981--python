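"""Diagnostic test evaluation: 2x2 metric battery, ROC and thresholds.

The positive class is SBT failure throughout, and a higher index value
predicts failure (every published index is higher in the failure group).
Proportion confidence intervals are exact Clopper-Pearson; likelihood-ratio
intervals use the standard log method; AUROC is the Mann-Whitney pair
statistic (ties count one half) with a DeLong variance for its interval and
the two-sided test against chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .indices import DomainError

CONFIDENCE = 0.95


@dataclass(frozen=True)
class Estimate:
    """Point estimate with a 95% confidence interval."""

    value: float
    lo: float
    hi: float

    def __post_init__(self):
        if not (math.isnan(self.lo) or math.isnan(self.hi)):
            if not self.lo <= self.value <= self.hi:
                raise ValueError(
                    f"CI ({self.lo}, {self.hi}) does not bracket {self.value}")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts; positive class = SBT failure."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DomainError("confusion counts must be non-negative")
        if self.total < 1:
            raise DomainError("confusion table must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Diagnostic-metric battery derived from one confusion table."""

    sensitivity: Estimate
    specificity: Estimate
    ppv: Estimate
    npv: Estimate
    accuracy: Estimate
    plr: Estimate
    nlr: Estimate
    dor: float
    f1: float
    mcc: float


def clopper_pearson(k: int, n: int, confidence: float = CONFIDENCE) -> Estimate:
    """Exact binomial proportion CI; degenerate 0/0 yields a NaN estimate."""
    if n == 0:
        return Estimate(math.nan, math.nan, math.nan)
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return Estimate(k / n, lo, hi)


def confusion_at(scores, labels, threshold: float,
                 direction: str = ">=") -> ConfusionCounts:
    """Dichotomize scores at a threshold and cross-tabulate against labels.

    Under the default direction, score >= threshold predicts the positive
    class (SBT failure).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DomainError("scores and labels must be equal-length 1-d arrays")
    if scores.size == 0:
        raise DomainError("empty input")
    if direction == ">=":
        pred = scores >= threshold
    elif direction == "<=":
        pred = scores <= threshold
    else:
        raise DomainError(f"unknown direction {direction!r}")
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def _lr_ci(point: float, log_var: float) -> Estimate:
    """Log-method CI for a likelihood ratio."""
    if not math.isfinite(point) or point <= 0 or not math.isfinite(log_var):
        return Estimate(point, point, point)
    z = stats.norm.ppf(0.5 + CONFIDENCE / 2)
    half = z * math.sqrt(log_var)
    return Estimate(point, point * math.exp(-half), point * math.exp(half))


def metric_set(c: ConfusionCounts) -> MetricSet:
    """Full metric battery from 2x2 counts.

    Degenerate denominators follow fixed conventions: MCC and F1 are 0 when
    a marginal is empty; infinite likelihood/odds ratios are returned as
    +inf rather than raising.
    """
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    sens = clopper_pearson(tp, tp + fn)
    spec = clopper_pearson(tn, tn + fp)
    ppv = clopper_pearson(tp, tp + fp)
    npv = clopper_pearson(tn, tn + fn)
    acc = clopper_pearson(tp + tn, c.total)

    if math.isnan(sens.value) or math.isnan(spec.value):
        plr_pt = nlr_pt = math.nan
    else:
        plr_pt = sens.value / (1 - spec.value) if spec.value < 1 else math.inf
        nlr_pt = (1 - sens.value) / spec.value if spec.value > 0 else math.inf
    plr_var = (_safe_inv(tp) - _safe_inv(tp + fn)
               + _safe_inv(fp) - _safe_inv(fp + tn))
    nlr_var = (_safe_inv(fn) - _safe_inv(tp + fn)
               + _safe_inv(tn) - _safe_inv(fp + tn))

    dor = (tp * tn) / (fp * fn) if fp > 0 and fn > 0 else (
        math.inf if tp * tn > 0 else math.nan)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = ((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / math.sqrt(denom)) if denom > 0 else 0.0

    return MetricSet(sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
                     accuracy=acc, plr=_lr_ci(plr_pt, plr_var),
                     nlr=_lr_ci(nlr_pt, nlr_var), dor=dor, f1=f1, mcc=mcc)


def _safe_inv(k: int) -> float:
    return 1.0 / k if k > 0 else math.inf


def predictive_values(sensitivity: float, specificity: float,
                      prevalence: float) -> tuple[float, float]:
    """PPV and NPV implied by sensitivity/specificity at a given prevalence."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1
            and 0 < prevalence < 1):
        raise DomainError("rates must be proportions, prevalence in (0, 1)")
    p, q = prevalence, 1 - prevalence
    ppv = sensitivity * p / (sensitivity * p + (1 - specificity) * q)
    npv = specificity * q / (specificity * q + (1 - sensitivity) * p)
    return ppv, npv


@dataclass(frozen=True)
class ROCCurve:
    """ROC curve on attained thresholds, with AUROC, DeLong CI and p-value.

    ``thresholds[0]`` is +inf (the (0, 0) corner); subsequent thresholds are
    the unique score values in descending order, so the final point is (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auroc: float
    auroc_ci: tuple[float, float]
    p_value: float

    def youden(self) -> np.ndarray:
        return self.tpr - self.fpr


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the AUROC via placement values."""
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(neg < p) + 0.5 * np.sum(neg == p)) / n
                    for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m
                    for q in neg])
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def mann_whitney_auroc(scores, labels) -> float:
    """AUROC as the tie-adjusted Mann-Whitney pair statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DomainError("AUROC requires both classes present")
    ranks = stats.rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    m, n = len(pos), len(neg)
    return float((r_pos - m * (m + 1) / 2) / (m * n))


def roc_curve(scores, labels) -> ROCCurve:
    """ROC over attained thresholds with DeLong interval and chance test."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DomainError("scores and labels must be equal-length 1-d arrays")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise DomainError("ROC requires both classes present")

    uniq = np.unique(scores)[::-1]  # descending
    thresholds = np.concatenate(([np.inf], uniq))
    tpr = np.array([np.mean(pos >= t) for t in thresholds])
    fpr = np.array([np.mean(neg >= t) for t in thresholds])

    auc = mann_whitney_auroc(scores, labels)
    var = _delong_variance(pos, neg)
    se = math.sqrt(var)
    z = stats.norm.ppf(0.5 + CONFIDENCE / 2)
    lo = min(max(auc - z * se, 0.0), 1.0)
    hi = min(max(auc + z * se, 0.0), 1.0)
    if se > 0:
        p = 2 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auroc=auc,
                    auroc_ci=(lo, hi), p_value=float(p))


def optimal_threshold(curve: ROCCurve) -> float:
    """Threshold maximizing Youden J = sens + spec - 1.

    Only attained score values are candidates (the +inf corner is excluded);
    ties are broken toward higher specificity, i.e. the higher threshold.
    """
    j = curve.youden()[1:]
    idx = int(np.argmax(j))  # argmax returns the first = highest threshold
    return float(curve.thresholds[1:][idx])
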