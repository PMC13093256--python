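"""Accuracy summaries, confusion matrices, ROC curves, and corrected
resampled-t confidence intervals.

Repeated random splits of a small cohort produce dependent accuracy
estimates; the corrected resampled t interval inflates the variance by
``1/n_splits + n_te/n_tr`` before applying the usual t quantile, giving
a conservative interval that accounts for the overlap between training
sets across splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitAccuracies",
    "corrected_resampled_ci",
    "confusion_matrix",
    "sensitivity_specificity",
    "roc_auc",
    "merge_roc",
]


@dataclass
class SplitAccuracies:
    """Per-split accuracies with the train/test sizes behind each value.

    ``values`` may be on the fraction (0-1) or percent (0-100) scale; the
    interval is scale-equivariant so the same units come back out.
    """

    values: np.ndarray
    n_tr: int
    n_te: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_tr < 1 or self.n_te < 1:
            raise ValueError("n_tr and n_te must be >= 1")

    @property
    def n_splits(self) -> int:
        return len(self.values)


def corrected_resampled_ci(
    acc: SplitAccuracies, level: float = 0.95
) -> tuple[float, float, float, float]:
    """(mean, sd, lower, upper) of the corrected resampled t interval.

    Half-width = ``sd * sqrt(1/n_splits + n_te/n_tr) * t_{df, q}`` with
    ``df = n_splits - 1`` and ``q = 1 - (1-level)/2``.  The interval is
    degenerate when sd = 0 and an error with a single split.
    """
    n = acc.n_splits
    if n < 2:
        raise ValueError("need at least two splits (sd undefined for one)")
    mean = float(acc.values.mean())
    sd = float(acc.values.std(ddof=1))
    tq = float(stats.t.ppf(1 - (1 - level) / 2, df=n - 1))
    half = sd * np.sqrt(1.0 / n + acc.n_te / acc.n_tr) * tq
    return mean, sd, mean - half, mean + half


def confusion_matrix(result, classes: list[str] | None = None) -> pd.DataFrame:
    """Class-by-class counts; rows are the true class, columns predicted."""
    records = result.records if hasattr(result, "records") else result
    if records.empty:
        raise ValueError("no predictions to tabulate")
    if classes is None:
        classes = sorted(set(records["true"]) | set(records["predicted"]))
    mat = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for _, row in records.iterrows():
        mat.loc[row["true"], row["predicted"]] += 1
    return mat


def sensitivity_specificity(result, positive_class: str) -> tuple[float, float]:
    """(sensitivity, specificity) = (TP/(TP+FN), TN/(TN+FP))."""
    records = result.records if hasattr(result, "records") else result
    true_pos = records["true"] == positive_class
    pred_pos = records["predicted"] == positive_class
    tp = int((true_pos & pred_pos).sum())
    fn = int((true_pos & ~pred_pos).sum())
    tn = int((~true_pos & ~pred_pos).sum())
    fp = int((~true_pos & pred_pos).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return sens, spec


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    from sklearn.metrics import roc_curve

    fpr, tpr, _ = roc_curve(labels, scores)
    return np.column_stack([fpr, tpr])


def roc_auc(scores, labels) -> float:
    """AUC by threshold sweep; ties count 1/2 (Mann-Whitney convention)."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, scores))


def merge_roc(per_split: list[tuple[np.ndarray, np.ndarray]]):
    """Per-split ROC/AUC plus the merged (pooled score-label) ROC/AUC.

    Splits whose labels contain a single class are skipped with a warning.
    Returns ``(per_split_points, per_split_aucs, merged_points, merged_auc)``.
    """
    points, aucs = [], []
    all_scores, all_labels = [], []
    for i, (scores, labels) in enumerate(per_split):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels)
        if len(np.unique(labels)) < 2:
            warnings.warn(f"split {i} has a single class; skipped", stacklevel=2)
            continue
        points.append(_roc_points(scores, labels))
        aucs.append(roc_auc(scores, labels))
        all_scores.append(scores)
        all_labels.append(labels)
    if not all_scores:
        raise ValueError("no split with both classes present")
    merged_scores = np.concatenate(all_scores)
    merged_labels = np.concatenate(all_labels)
    merged_points = _roc_points(merged_scores, merged_labels)
    merged_auc = roc_auc(merged_scores, merged_labels)
    return points, aucs, merged_points, merged_auc
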