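"""Evaluation metrics and differential-composition statistics.

The four classification metrics — sensitivity, specificity, accuracy and
the Matthews correlation coefficient — are computed from per-class error
counts in the Chou-style form: with N+ the number of true ACPs, N- the
number of true non-ACPs, N-+ the ACPs predicted as non-ACPs and N+- the
non-ACPs predicted as ACPs,

    Sn  = 1 - N-+/N+
    Sp  = 1 - N+-/N-
    Acc = 1 - (N-+ + N+-)/(N+ + N-)
    MCC = (1 - (N-+/N+ + N+-/N-))
          / sqrt((1 + (N+- - N-+)/N+) (1 + (N-+ - N+-)/N-))

These are algebraically identical to the classical TP/TN/FP/FN formulas;
the test suite verifies the equivalence exhaustively.

Differential-composition analysis compares per-column feature means of two
groups (e.g. ACP vs non-ACP dipeptide compositions) by Welch's unequal-
variance t test at a raw p < 0.01 threshold, no multiple-testing correction
by default (an optional Bonferroni flag is provided).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary-classification error counts in per-class form.

    n_pos / n_neg are the true class sizes; false_neg is the number of
    positives predicted negative (N-+), false_pos the negatives predicted
    positive (N+-).
    """

    n_pos: int
    n_neg: int
    false_neg: int
    false_pos: int

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("class sizes must be non-negative")
        if self.n_pos + self.n_neg < 1:
            raise ValueError("at least one sample required")
        if not 0 <= self.false_neg <= self.n_pos:
            raise ValueError("false_neg out of range")
        if not 0 <= self.false_pos <= self.n_neg:
            raise ValueError("false_pos out of range")

    @property
    def tp(self) -> int:
        return self.n_pos - self.false_neg

    @property
    def tn(self) -> int:
        return self.n_neg - self.false_pos


@dataclass(frozen=True)
class MetricSet:
    """Sensitivity, specificity, accuracy (fractions) and MCC.

    A metric undefined for the given counts (one class empty, or a
    degenerate MCC denominator) is ``None`` rather than NaN;
    ``mcc_degenerate`` flags the MCC = 0 convention for a degenerate
    (single-column) prediction.
    """

    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: float
    mcc: Optional[float]
    mcc_degenerate: bool = False


def confusion_counts(
    true_labels: Sequence[int], predicted_labels: Sequence[int]
) -> ConfusionCounts:
    """Tabulate per-class error counts from binary label vectors."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("label vectors must be 1-D and equal length")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionCounts(
        n_pos=int((y == 1).sum()),
        n_neg=int((y == 0).sum()),
        false_neg=int(((y == 1) & (p == 0)).sum()),
        false_pos=int(((y == 0) & (p == 1)).sum()),
    )


def chou_metrics(counts: ConfusionCounts) -> MetricSet:
    """Compute the metric set from error counts, Chou-style formulas."""
    npos, nneg = counts.n_pos, counts.n_neg
    fn, fp = counts.false_neg, counts.false_pos
    sn = 1.0 - fn / npos if npos else None
    sp = 1.0 - fp / nneg if nneg else None
    acc = 1.0 - (fn + fp) / (npos + nneg)
    mcc: Optional[float] = None
    degenerate = False
    if npos and nneg:
        denom_sq = (1.0 + (fp - fn) / npos) * (1.0 + (fn - fp) / nneg)
        if denom_sq <= 0:
            # happens only when a predicted class is empty: MCC := 0
            mcc, degenerate = 0.0, True
        else:
            mcc = (1.0 - (fn / npos + fp / nneg)) / math.sqrt(denom_sq)
    return MetricSet(sn, sp, acc, mcc, degenerate)


@dataclass(frozen=True)
class WelchResult:
    t: Optional[float]
    df: Optional[float]
    p: Optional[float]


def welch_t(
    group_a: Sequence[float], group_b: Sequence[float]
) -> WelchResult:
    """Welch's unequal-variance t test, two-sided.

    Returns the t statistic, Welch-Satterthwaite degrees of freedom and the
    two-sided p-value; all ``None`` when a group has fewer than two values
    or both groups have zero variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return WelchResult(None, None, None)
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        return WelchResult(None, None, None)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def differential_features(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Columns whose group means differ at p < alpha by Welch's t test.

    Both matrices must share column names (rows = samples). Returns a
    DataFrame with columns ``feature``, ``t``, ``p``, ``mean_diff``
    (group a minus group b), sorted by ``|mean_diff|`` descending. With
    ``bonferroni=True`` the threshold becomes alpha / n_columns.
    """
    if list(matrix_a.columns) != list(matrix_b.columns):
        raise ValueError("feature matrices have different columns")
    a = matrix_a.to_numpy(dtype=float)
    b = matrix_b.to_numpy(dtype=float)
    res = stats.ttest_ind(a, b, axis=0, equal_var=False)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    diff = a.mean(axis=0) - b.mean(axis=0)
    # constant identical columns: scipy yields NaN; no evidence of difference
    p = np.where(np.isnan(p), 1.0, p)
    threshold = alpha / len(matrix_a.columns) if bonferroni else alpha
    table = pd.DataFrame(
        {
            "feature": matrix_a.columns,
            "t": t,
            "p": p,
            "mean_diff": diff,
        }
    )
    table = table[table["p"] < threshold]
    table = table.reindex(
        table["mean_diff"].abs().sort_values(ascending=False).index
    )
    return table.reset_index(drop=True)


def metrics_row(metrics: MetricSet, model: str = "", dataset: str = "") -> dict:
    """Flatten a MetricSet into a report row (TSV/JSON friendly)."""
    return {
        "model": model,
        "dataset": dataset,
        "mcc": metrics.mcc,
        "accuracy": metrics.accuracy,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
    }
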