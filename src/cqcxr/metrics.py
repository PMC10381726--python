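"""Evaluation metrics, fold aggregation and statistical comparisons.

The metric set mirrors what is conventionally reported for a balanced
binary screening task: ROC AUC, accuracy, balanced accuracy and per-class
precision/recall (precision 0 = negative predictive value, recall 0 =
specificity, recall 1 = sensitivity). Fold means carry t-based 95%
confidence intervals. Model comparisons use a paired t-test across folds;
contingency tables use Pearson chi-square without continuity correction;
group summaries (e.g. age by class) use Welch's t-test from summary
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "MetricsReport",
    "FoldSummary",
    "ComparisonResult",
    "compute_metrics",
    "paired_t_test",
    "chi_square_2x2",
    "welch_t_from_summary",
    "summarize_folds",
    "roc_points",
]

METRIC_NAMES = (
    "auc",
    "accuracy",
    "balanced_accuracy",
    "precision_0",
    "precision_1",
    "recall_0",
    "recall_1",
)


@dataclass(frozen=True)
class MetricsReport:
    """The seven headline metrics for one evaluation.

    An undefined precision (no sample predicted in that class) is reported
    as NaN with the corresponding flag set, never silently as 0.
    """

    auc: float
    accuracy: float
    balanced_accuracy: float
    precision_0: float
    precision_1: float
    recall_0: float
    recall_1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class FoldSummary:
    """Per-metric mean and 95% CI (t-distribution, k-1 df) over folds."""

    reports: tuple[MetricsReport, ...]
    mean: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "metric": list(METRIC_NAMES),
                "mean": [self.mean[m] for m in METRIC_NAMES],
                "ci_low": [self.ci_low[m] for m in METRIC_NAMES],
                "ci_high": [self.ci_high[m] for m in METRIC_NAMES],
            }
        )


@dataclass(frozen=True)
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    df: float
    degenerate: bool = False


def compute_metrics(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricsReport:
    """Metrics from true 0/1 labels and probability-of-class-1 scores.

    AUC is the Mann-Whitney rank statistic with half credit for ties
    (``sklearn.metrics.roc_auc_score``); thresholded metrics use
    ``scores >= threshold`` as the positive prediction.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must have the same shape")
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present (AUC undefined otherwise)")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must be probabilities in [0, 1]")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    undefined = []
    if tn + fn == 0:
        precision_0, undefined = np.nan, undefined + ["precision_0"]
    else:
        precision_0 = tn / (tn + fn)
    if tp + fp == 0:
        precision_1, undefined = np.nan, undefined + ["precision_1"]
    else:
        precision_1 = tp / (tp + fp)
    recall_0 = tn / (tn + fp)
    recall_1 = tp / (tp + fn)
    return MetricsReport(
        auc=float(roc_auc_score(labels, scores)),
        accuracy=(tp + tn) / labels.size,
        balanced_accuracy=(recall_0 + recall_1) / 2.0,
        precision_0=precision_0,
        precision_1=precision_1,
        recall_0=recall_0,
        recall_1=recall_1,
        undefined=tuple(undefined),
    )


def paired_t_test(values_a: Sequence[float], values_b: Sequence[float]) -> ComparisonResult:
    """Two-sided paired t-test on per-fold metric values.

    All-zero differences give (t=0, p=1); a nonzero constant difference has
    zero variance and is flagged degenerate (p set to 0, the limit).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    k = a.size
    if k < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return ComparisonResult("paired_t", 0.0, 1.0, k - 1)
        return ComparisonResult("paired_t", np.inf, 0.0, k - 1, degenerate=True)
    t = d.mean() / (sd / np.sqrt(k))
    p = 2.0 * stats.t.sf(abs(t), k - 1)
    return ComparisonResult("paired_t", float(t), float(p), k - 1)


def chi_square_2x2(table: np.ndarray) -> ComparisonResult:
    """Pearson chi-square on a 2x2 contingency table, df=1, no continuity
    correction."""
    table = np.asarray(table)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("table must hold nonnegative integer counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("all marginals must be positive")
    res = stats.chi2_contingency(table, correction=False)
    return ComparisonResult("chi_square_2x2", float(res.statistic), float(res.pvalue), 1.0)


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> ComparisonResult:
    """Welch two-sample t-test from summary statistics, Satterthwaite df."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both groups")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return ComparisonResult("welch_t_summary", float(res.statistic), float(res.pvalue), float(df))


def summarize_folds(reports: Sequence[MetricsReport]) -> FoldSummary:
    """Mean +/- t_{0.975,k-1} * sd / sqrt(k) per metric over >= 2 folds."""
    if len(reports) < 2:
        raise ValueError("need at least 2 folds")
    k = len(reports)
    tq = stats.t.ppf(0.975, k - 1)
    mean: dict[str, float] = {}
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        if np.all(np.isnan(vals)):  # metric undefined in every fold
            mean[name] = lo[name] = hi[name] = np.nan
            continue
        m = float(np.nanmean(vals))
        half = float(tq * np.nanstd(vals, ddof=1) / np.sqrt(k))
        mean[name], lo[name], hi[name] = m, m - half, m + half
    return FoldSummary(tuple(reports), mean, lo, hi)


def roc_points(labels: np.ndarray, scores: np.ndarray) -> pd.DataFrame:
    """ROC curve samples as a (fpr, tpr, threshold) table."""
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
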