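"""Diagnostic-accuracy evaluation: ROC/AUC, optimal threshold, confusion
metrics, and stratified bootstrap confidence intervals.

Conventions, fixed and documented because published reports rarely state
them:

* prediction rule at threshold t: probability >= t => positive call;
* AUC by the trapezoid over all unique score thresholds, identical to the
  Mann-Whitney U statistic divided by n_pos * n_neg with ties counted 1/2;
* "optimal" threshold maximizes Youden's J = sensitivity + specificity - 1,
  ties resolved to the smallest qualifying threshold;
* 95% intervals are percentile bootstrap over class-stratified resamples
  (B = 2000), seeded;
* reported metrics are rounded to 2 decimals, round-half-up, with full
  precision retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable

import numpy as np


def round2(x: float | None) -> float | None:
    """Round-half-up to 2 decimals (report rendering)."""
    if x is None:
        return None
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class ROCResult:
    """ROC curve with AUC and optional 95% CI.

    ``thresholds`` are the unique scores in descending order; ``fpr`` and
    ``tpr`` are aligned with them and are non-decreasing as the threshold
    decreases. The curve implicitly starts at (0, 0) (threshold above every
    score) and the arrays end at (1, 1).
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError("AUC must lie in [0, 1]")
        if self.ci is not None and not self.ci[0] <= self.auc <= self.ci[1]:
            raise ValueError("CI must bracket the AUC point estimate")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for a declared positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = "positive"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn


@dataclass
class DiagnosticReport:
    """Point estimates (with optional CIs) of the standard accuracy panel.

    Zero-denominator metrics are ``None`` ("undefined"), never 0.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    confusion: ConfusionCounts
    auc: float | None = None
    threshold: float | None = None
    auc_ci: tuple[float, float] | None = None
    sensitivity_ci: tuple[float, float] | None = None
    specificity_ci: tuple[float, float] | None = None
    ppv_ci: tuple[float, float] | None = None
    npv_ci: tuple[float, float] | None = None

    def rounded(self) -> dict[str, float | None]:
        return {
            "auc": round2(self.auc),
            "sensitivity": round2(self.sensitivity),
            "specificity": round2(self.specificity),
            "ppv": round2(self.ppv),
            "npv": round2(self.npv),
        }

    def summary(self, comparison: str = "", classifier: str = "") -> str:
        """One Table-style report row: metric (95% CI) per column."""

        def cell(value: float | None, ci: tuple[float, float] | None) -> str:
            if value is None:
                return "undefined"
            s = f"{round2(value):.2f}"
            if ci is not None:
                s += f"({round2(ci[0]):.2f}-{round2(ci[1]):.2f})"
            return s

        header = f"{'Comparison':<28}{'Classifier':<20}{'AUC':<18}{'Sens':<18}{'Spec':<18}{'PPV':<18}{'NPV':<18}"
        row = (
            f"{comparison:<28}{classifier:<20}"
            f"{cell(self.auc, self.auc_ci):<18}"
            f"{cell(self.sensitivity, self.sensitivity_ci):<18}"
            f"{cell(self.specificity, self.specificity_ci):<18}"
            f"{cell(self.ppv, self.ppv_ci):<18}"
            f"{cell(self.npv, self.npv_ci):<18}"
        )
        return header + "\n" + row


def _check_binary(proba: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    proba = np.asarray(proba, dtype=float)
    labels = np.asarray(labels).astype(int)
    if proba.shape != labels.shape or proba.ndim != 1:
        raise ValueError("probabilities and labels must be equal-length 1D arrays")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return proba, labels


def roc_auc(proba: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and trapezoidal AUC over all unique score thresholds.

    Equivalent to the rank (Mann-Whitney) formulation: the probability a
    random positive outscores a random negative, ties counted 1/2.
    """
    proba, labels = _check_binary(proba, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    order = np.argsort(-proba, kind="stable")
    sorted_p = proba[order]
    sorted_y = labels[order]
    # cumulative TP/FP at score >= threshold, taken at the end of each
    # block of tied scores
    last = np.flatnonzero(np.r_[sorted_p[1:] != sorted_p[:-1], True])
    thresholds = sorted_p[last]
    tpr = np.cumsum(sorted_y)[last] / n_pos
    fpr = np.cumsum(1 - sorted_y)[last] / n_neg
    auc = float(np.trapezoid(np.r_[0.0, tpr], np.r_[0.0, fpr]))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def optimal_threshold(roc: ROCResult) -> float:
    """Threshold maximizing Youden's J; ties -> the smallest threshold.

    Returned values are actual observed scores (the prediction rule is
    ``proba >= t``), so the choice is deterministic even when J is flat.
    """
    j = roc.tpr - roc.fpr
    best = np.flatnonzero(j == j.max())
    # thresholds are descending, so the last best index is the smallest
    return float(roc.thresholds[best[-1]])


def confusion_at_threshold(
    proba: np.ndarray, labels: np.ndarray, threshold: float, positive_class: str = "positive"
) -> ConfusionCounts:
    """Apply the ``proba >= threshold`` rule and count the 2x2 table."""
    proba, labels = _check_binary(proba, labels)
    pred = proba >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        fp=int(np.sum(pred & (labels == 0))),
        tn=int(np.sum(~pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
        positive_class=positive_class,
    )


def confusion_from_counts(
    fp: int, fn: int, n_pos: int, n_neg: int, positive_class: str = "positive"
) -> ConfusionCounts:
    """Reconstruct the full 2x2 table from published FP/FN counts and the
    group sizes: tp = n_pos - fn, tn = n_neg - fp."""
    if not 0 <= fp <= n_neg:
        raise ValueError("need 0 <= fp <= n_neg")
    if not 0 <= fn <= n_pos:
        raise ValueError("need 0 <= fn <= n_pos")
    return ConfusionCounts(
        tp=n_pos - fn, fp=fp, tn=n_neg - fp, fn=fn, positive_class=positive_class
    )


def metrics_from_confusion(c: ConfusionCounts) -> DiagnosticReport:
    """Sensitivity, specificity, PPV and NPV from a 2x2 table.

    sens = tp/(tp+fn); spec = tn/(tn+fp); PPV = tp/(tp+fp);
    NPV = tn/(tn+fn). A zero denominator yields ``None``.
    """

    def ratio(num: int, den: int) -> float | None:
        return num / den if den > 0 else None

    return DiagnosticReport(
        sensitivity=ratio(c.tp, c.tp + c.fn),
        specificity=ratio(c.tn, c.tn + c.fp),
        ppv=ratio(c.tp, c.tp + c.fp),
        npv=ratio(c.tn, c.tn + c.fn),
        confusion=c,
    )


MetricFn = Callable[[np.ndarray, np.ndarray], float]


def metric_auc(proba: np.ndarray, labels: np.ndarray) -> float:
    return roc_auc(proba, labels).auc


def make_threshold_metric(name: str, threshold: float) -> MetricFn:
    """Metric closure evaluating one accuracy metric at a fixed threshold."""

    def fn(proba: np.ndarray, labels: np.ndarray) -> float:
        report = metrics_from_confusion(
            confusion_at_threshold(proba, labels, threshold)
        )
        value = getattr(report, name)
        return float("nan") if value is None else float(value)

    return fn


def bootstrap_ci(
    proba: np.ndarray,
    labels: np.ndarray,
    metric: MetricFn,
    B: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap interval over class-stratified resamples.

    Positives and negatives are resampled separately with replacement, so
    every replicate contains both classes by construction (a replicate
    that nevertheless degenerates — e.g. an undefined metric — is redrawn,
    up to a bounded number of retries). Reproducible given ``seed``.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    proba, labels = _check_binary(proba, labels)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    values = np.empty(B)
    for b in range(B):
        for _ in range(100):  # redraw guard for degenerate replicates
            idx = np.r_[
                rng.choice(pos, size=pos.size, replace=True),
                rng.choice(neg, size=neg.size, replace=True),
            ]
            v = metric(proba[idx], labels[idx])
            if np.isfinite(v):
                values[b] = v
                break
        else:
            values[b] = np.nan
    values = values[np.isfinite(values)]
    lo, hi = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def evaluate_scores(
    proba: np.ndarray,
    labels: np.ndarray,
    threshold: float | None = None,
    positive_class: str = "positive",
    B: int = 2000,
    seed: int = 0,
) -> DiagnosticReport:
    """Full diagnostic report from collated scores.

    Computes the ROC and AUC, picks the Youden-optimal threshold (unless
    one is supplied), derives the confusion table and the accuracy panel,
    and attaches stratified-bootstrap 95% CIs to every metric.
    """
    roc = roc_auc(proba, labels)
    t = optimal_threshold(roc) if threshold is None else float(threshold)
    confusion = confusion_at_threshold(proba, labels, t, positive_class)
    report = metrics_from_confusion(confusion)
    report.auc = roc.auc
    report.threshold = t
    report.auc_ci = bootstrap_ci(proba, labels, metric_auc, B=B, seed=seed)
    for name in ("sensitivity", "specificity", "ppv", "npv"):
        ci = bootstrap_ci(
            proba, labels, make_threshold_metric(name, t), B=B, seed=seed
        )
        setattr(report, f"{name}_ci", ci)
    return report
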