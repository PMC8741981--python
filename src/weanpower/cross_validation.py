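"""Repeated stratified k-fold cross-validation with threshold learning.

For each repeat and fold the operating threshold is learned on the training
fold alone (Youden-optimal point of the training ROC) and evaluated on the
held-out fold, so the reported metric battery is prospective: no test-fold
information ever reaches threshold selection.  The default configuration is
the study's 2-times repeated, stratified 2-fold layout.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field

import numpy as np

from .diagnostic_metrics import (ConfusionCounts, Estimate, MetricSet,
                                 confusion_at, metric_set, optimal_threshold,
                                 roc_curve)
from .indices import DomainError, FAILURE, IndexPanel, PatientRecord, compute_panel

logger = logging.getLogger(__name__)

PROPORTION_METRICS = ("sensitivity", "specificity", "ppv", "npv", "accuracy")
RATIO_METRICS = ("plr", "nlr")
SCALAR_METRICS = ("dor", "f1", "mcc")


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation layout and threshold rule."""

    k: int = 2
    repeats: int = 2
    seed: int = 0
    threshold_rule: str = "youden"
    index_name: str = "pi_1"
    aggregation: str = "mean"  # "mean" over folds, or "pooled" counts

    def __post_init__(self):
        if self.k < 2:
            raise DomainError(f"k must be at least 2, got {self.k}")
        if self.repeats < 1:
            raise DomainError(f"repeats must be at least 1, got {self.repeats}")
        if self.threshold_rule != "youden":
            raise DomainError(f"unknown threshold rule {self.threshold_rule!r}")
        if self.aggregation not in ("mean", "pooled"):
            raise DomainError(f"unknown aggregation {self.aggregation!r}")


@dataclass(frozen=True)
class FoldResult:
    repeat: int
    fold: int
    learned_threshold: float
    counts: ConfusionCounts
    metrics: MetricSet


@dataclass(frozen=True)
class CVResult:
    """Per-fold records plus across-fold summaries."""

    folds: list[FoldResult]
    mean_threshold: float
    mean_metrics: MetricSet
    config: CVConfig
    excluded_folds: int = 0


def stratified_partition(labels, k: int, seed: int) -> np.ndarray:
    """Assign each case to one of k folds, stratified by label.

    Fold sizes differ by at most one both overall and within each class;
    the assignment is reproducible for a fixed seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        raise DomainError("empty label vector")
    rng = np.random.default_rng(seed)
    assignment = np.full(n, -1, dtype=int)
    fold_sizes = np.zeros(k, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            raise DomainError(
                f"class {cls!r} has {len(idx)} members, fewer than k={k}")
        rng.shuffle(idx)
        base, extra = divmod(len(idx), k)
        # give the remainder to the currently smallest folds so the overall
        # size spread stays within one
        order = np.lexsort((rng.permutation(k), fold_sizes))
        counts = np.full(k, base, dtype=int)
        counts[order[:extra]] += 1
        start = 0
        for fold in range(k):
            assignment[idx[start:start + counts[fold]]] = fold
            start += counts[fold]
        fold_sizes += counts
    return assignment


def _mean_estimate(estimates: list[Estimate]) -> Estimate:
    """Unweighted mean of fold-level points and CI bounds (NaNs dropped)."""
    vals = [e.value for e in estimates if not math.isnan(e.value)]
    los = [e.lo for e in estimates if not math.isnan(e.lo)]
    his = [e.hi for e in estimates if not math.isnan(e.hi)]
    if not vals:
        return Estimate(math.nan, math.nan, math.nan)
    return Estimate(statistics.fmean(vals), statistics.fmean(los),
                    statistics.fmean(his))


def _mean_scalar(values: list[float]) -> float:
    finite = [v for v in values if math.isfinite(v)]
    return statistics.fmean(finite) if finite else math.nan


def _aggregate(folds: list[FoldResult], aggregation: str) -> MetricSet:
    if aggregation == "pooled":
        pooled = ConfusionCounts(
            tp=sum(f.counts.tp for f in folds),
            fp=sum(f.counts.fp for f in folds),
            fn=sum(f.counts.fn for f in folds),
            tn=sum(f.counts.tn for f in folds))
        return metric_set(pooled)
    kwargs = {}
    for name in PROPORTION_METRICS + RATIO_METRICS:
        kwargs[name] = _mean_estimate([getattr(f.metrics, name) for f in folds])
    for name in SCALAR_METRICS:
        kwargs[name] = _mean_scalar([getattr(f.metrics, name) for f in folds])
    return MetricSet(**kwargs)


def run_cv_scores(scores, labels, config: CVConfig) -> CVResult:
    """Cross-validate a scalar index given per-case scores and labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DomainError("scores and labels must be equal-length 1-d arrays")
    if len(np.unique(labels)) < 2:
        raise DomainError("cross-validation requires both outcomes present")

    folds: list[FoldResult] = []
    excluded = 0
    for rep in range(config.repeats):
        assignment = stratified_partition(labels, config.k,
                                          seed=config.seed + rep)
        for fold in range(config.k):
            test = assignment == fold
            train = ~test
            threshold = optimal_threshold(roc_curve(scores[train], labels[train]))
            if len(np.unique(labels[test])) < 2:
                logger.warning("repeat %d fold %d has a single-class test "
                               "fold; excluded from aggregation", rep, fold)
                excluded += 1
                continue
            counts = confusion_at(scores[test], labels[test], threshold)
            folds.append(FoldResult(repeat=rep, fold=fold,
                                    learned_threshold=threshold,
                                    counts=counts, metrics=metric_set(counts)))
    if not folds:
        raise DomainError("every test fold was degenerate")
    mean_thr = statistics.fmean(f.learned_threshold for f in folds)
    return CVResult(folds=folds, mean_threshold=mean_thr,
                    mean_metrics=_aggregate(folds, config.aggregation),
                    config=config, excluded_folds=excluded)


def run_cv(cohort: list[PatientRecord], config: CVConfig) -> CVResult:
    """Cross-validate one index of the panel over a patient cohort."""
    scores, labels = index_scores(cohort, config.index_name)
    return run_cv_scores(scores, labels, config)


def index_scores(cohort: list[PatientRecord],
                 index_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract an index (panel field or record field) and failure labels."""
    if not cohort:
        raise DomainError("empty cohort")
    values = []
    labels = []
    panel_fields = set(IndexPanel.__dataclass_fields__)
    for rec in cohort:
        if rec.sbt_outcome is None:
            raise DomainError(f"patient {rec.patient_id} has no SBT outcome")
        if index_name in panel_fields:
            values.append(getattr(compute_panel(rec), index_name))
        elif hasattr(rec, index_name):
            values.append(float(getattr(rec, index_name)))
        else:
            raise DomainError(f"unknown index {index_name!r}")
        labels.append(1 if rec.sbt_outcome == FAILURE else 0)
    return np.asarray(values, dtype=float), np.asarray(labels, dtype=int)
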