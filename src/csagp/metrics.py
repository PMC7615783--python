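"""Confusion-matrix metrics and ROC AUC.

accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN),
specificity = TN/(FP+TN); AUC is the area under the ROC curve, computed
here through the rank-statistic (Mann-Whitney) identity with midrank tie
handling, which equals the trapezoidal area under the empirical ROC.

For more than two classes each metric is macro-averaged one-vs-rest; this
aggregation choice is recorded in the report itself since the reference
tables' multiclass rows depend on it.  A class absent from ``y_true`` has
undefined sensitivity and AUC: its entries are reported as missing (None)
and excluded from the macro average, never silently zeroed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["ConfusionCounts", "confusion_counts", "binary_auc",
           "compute_metrics", "write_report", "write_history"]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float | None:
        pos = self.tp + self.fn
        return self.tp / pos if pos else None

    @property
    def specificity(self) -> float | None:
        neg = self.tn + self.fp
        return self.tn / neg if neg else None


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray,
                     positive) -> ConfusionCounts:
    """One-vs-rest confusion counts for the given positive label."""
    t = np.asarray(y_true) == positive
    p = np.asarray(y_pred) == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)), tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)), fn=int(np.sum(t & ~p)))


def binary_auc(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """ROC AUC via midranks; None if only one class is present."""
    y = np.asarray(y_true, dtype=bool)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(np.asarray(scores, dtype=float))
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_metrics(y_true: np.ndarray, y_prob: np.ndarray,
                    classes: np.ndarray | None = None) -> dict:
    """Accuracy, sensitivity, specificity and AUC from labels and
    predicted class probabilities (n_samples x n_classes).

    Binary tasks treat the second class (column 1) as positive.  Multiclass
    tasks macro-average one-vs-rest; the ``aggregation`` field of the
    returned report states which convention applied.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_prob.ndim != 2 or len(y_true) != len(y_prob):
        raise ValueError("y_prob must be (n_samples, n_classes) aligned with y_true")
    n_classes = y_prob.shape[1]
    if classes is None:
        classes = np.arange(n_classes)
    if len(classes) != n_classes:
        raise ValueError("classes length must match y_prob columns")
    y_pred = np.asarray(classes)[np.argmax(y_prob, axis=1)]

    accuracy = float(np.mean(y_true == y_pred))
    per_class: dict = {}
    missing: list = []
    for j, c in enumerate(classes):
        counts = confusion_counts(y_true, y_pred, c)
        auc = binary_auc(y_true == c, y_prob[:, j])
        per_class[str(c)] = {
            "sensitivity": counts.sensitivity,
            "specificity": counts.specificity,
            "auc": auc,
            "support": int(np.sum(y_true == c)),
        }
        if counts.sensitivity is None or auc is None:
            missing.append(c)

    if n_classes == 2:
        pos = str(classes[1])
        report = {
            "accuracy": accuracy,
            "sensitivity": per_class[pos]["sensitivity"],
            "specificity": per_class[pos]["specificity"],
            "auc": per_class[pos]["auc"],
            "aggregation": f"binary (positive class = {classes[1]})",
        }
    else:
        def macro(key):
            vals = [v[key] for v in per_class.values() if v[key] is not None]
            return float(np.mean(vals)) if vals else None

        report = {
            "accuracy": accuracy,
            "sensitivity": macro("sensitivity"),
            "specificity": macro("specificity"),
            "auc": macro("auc"),
            "aggregation": "macro one-vs-rest",
        }
    report["per_class"] = per_class
    report["n_samples"] = int(len(y_true))
    if missing:
        report["missing_classes"] = [str(c) for c in missing]
    return report


def write_report(report: dict, json_path: str | None = None,
                 csv_path: str | None = None) -> None:
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(report, fh, indent=2)
    if csv_path:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["metric", "value"])
            for key in ("accuracy", "sensitivity", "specificity", "auc"):
                writer.writerow([key, report.get(key)])


def write_history(history: list[dict], csv_path: str) -> None:
    """Per-epoch training log as CSV."""
    if not history:
        return
    keys = list(history[0].keys())
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(history)
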