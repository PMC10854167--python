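"""Train/validation splitting and performance summaries.

Reports follow the clinical-classifier convention: a confusion matrix
with true classes in rows and predicted classes in columns (counts and a
row-percent view), one-vs-rest sensitivity/specificity/PPV/NPV per class,
and overall accuracy. Undefined ratios (0/0, e.g. PPV of a class never
predicted) are reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import SampleLabels

__all__ = [
    "ConfusionMatrix",
    "stratified_split",
    "confusion_matrix",
    "per_class_metrics",
    "evaluation_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    classes: list[str]
    counts: pd.DataFrame  # true x predicted, integer counts

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts.to_numpy()) / self.total)

    def row_percent(self) -> pd.DataFrame:
        """100 * count / row sum; all-zero rows stay zero."""
        c = self.counts.to_numpy(dtype=float)
        sums = c.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            pct = np.where(sums > 0, 100.0 * c / sums, 0.0)
        return pd.DataFrame(pct, index=self.counts.index,
                            columns=self.counts.columns)


def stratified_split(labels: SampleLabels, train_frac: float = 0.30,
                     seed: int = 0):
    """Stratified random split into (train_ids, valid_ids).

    Per class c with n_c samples, ``ceil(train_frac * n_c)`` go to
    training (clamped to [1, n_c - 1] so both partitions see every class
    when n_c >= 2). The partitions are disjoint and exhaustive.
    """
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, valid = [], []
    for cls, n_c in labels.class_counts().items():
        if n_c < 2:
            raise ValueError(f"class {cls!r} has {n_c} sample(s); "
                             "need >=2 to split")
        ids = [s for s in labels.sample_ids if labels.mapping[s] == cls]
        perm = rng.permutation(len(ids))
        n_train = min(max(math.ceil(train_frac * n_c), 1), n_c - 1)
        train.extend(ids[i] for i in perm[:n_train])
        valid.extend(ids[i] for i in perm[n_train:])
    return sorted(train), sorted(valid)


def confusion_matrix(true_labels, predicted_labels,
                     classes=None) -> ConfusionMatrix:
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    if not true_labels:
        raise ValueError("empty input")
    if classes is None:
        classes = sorted(set(true_labels) | set(predicted_labels))
    classes = list(classes)
    unknown = (set(true_labels) | set(predicted_labels)) - set(classes)
    if unknown:
        raise ValueError(f"labels outside the class order: {sorted(unknown)}")
    idx = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(classes, pd.DataFrame(
        counts, index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted")))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """One-vs-rest sensitivity, specificity, PPV and NPV per class.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    PPV = TP/(TP+FP); NPV = TN/(TN+FN).
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    c = cm.counts.to_numpy(dtype=float)
    total = c.sum()
    rows = []
    for i, cls in enumerate(cm.classes):
        tp = c[i, i]
        fn = c[i].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        rows.append({
            "class": cls,
            "sensitivity": _ratio(tp, tp + fn),
            "specificity": _ratio(tn, tn + fp),
            "ppv": _ratio(tp, tp + fp),
            "npv": _ratio(tn, tn + fn),
        })
    return pd.DataFrame(rows).set_index("class")


def evaluation_report(true_labels, predicted_labels, classes=None) -> dict:
    """Confusion matrix, per-class metrics and overall accuracy in one call."""
    cm = confusion_matrix(true_labels, predicted_labels, classes)
    return {"confusion": cm, "metrics": per_class_metrics(cm),
            "accuracy": cm.accuracy}
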