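"""Confusion-matrix metrics, regression error, and k-fold reporting.

Classification metrics follow the usual confusion-count definitions:
accuracy ``(TP+TN)/(TP+TN+FP+FN)``, sensitivity (= recall) ``TP/(TP+FN)``,
F-measure as the harmonic mean of precision and recall.  Two specificity
variants are exposed: ``standard`` is the conventional ``TN/(TN+FP)``;
``paper`` is ``TP/(TP+FP)`` — algebraically precision — matching a
definition that circulates in parts of the diagnostic-imaging literature.
``standard`` is the default everywhere.

Undefined metrics (zero denominators) are reported as ``None`` and
excluded from fold means, never coerced to 0.

Multiclass problems are scored one-vs-rest per class and macro-averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FoldAssignment",
    "confusion_counts",
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f_measure",
    "rmse",
    "r_squared",
    "macro_metrics",
    "kfold_split",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Per-fold metric rows plus their mean (None entries excluded)."""

    folds: list[dict] = field(default_factory=list)

    @property
    def mean(self) -> dict:
        if not self.folds:
            return {}
        keys = self.folds[0].keys()
        out = {}
        for k in keys:
            vals = [f[k] for f in self.folds if f.get(k) is not None]
            out[k] = float(np.mean(vals)) if vals else None
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [dict(f, fold=i) for i, f in enumerate(self.folds)]
        rows.append(dict(self.mean, fold="mean"))
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of: np.ndarray  # per-sample fold index in [0, k)

    def indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, val_idx): train on k-1 folds, validate on one."""
        val = np.flatnonzero(self.fold_of == fold)
        train = np.flatnonzero(self.fold_of != fold)
        return train, val


def confusion_counts(predictions, truths, positive_class) -> ConfusionCounts:
    """One-vs-rest counts for the named positive class."""
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal length")
    if predictions.size == 0:
        raise ValueError("cannot count an empty label sequence")
    pred_pos = predictions == positive_class
    true_pos = truths == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & true_pos)),
        fp=int(np.sum(pred_pos & ~true_pos)),
        tn=int(np.sum(~pred_pos & ~true_pos)),
        fn=int(np.sum(~pred_pos & true_pos)),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ValueError("accuracy undefined for zero samples")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float | None:
    """Recall; None when there are no positive samples."""
    denom = c.tp + c.fn
    return c.tp / denom if denom else None


def precision(c: ConfusionCounts) -> float | None:
    denom = c.tp + c.fp
    return c.tp / denom if denom else None


def specificity(c: ConfusionCounts, mode: str = "standard") -> float | None:
    """``standard``: TN/(TN+FP).  ``paper``: TP/(TP+FP) (i.e. precision)."""
    if mode == "standard":
        denom = c.tn + c.fp
        return c.tn / denom if denom else None
    if mode == "paper":
        return precision(c)
    raise ValueError(f"unknown specificity mode {mode!r}")


def f_measure(c: ConfusionCounts) -> float | None:
    p = precision(c)
    r = sensitivity(c)
    if p is None or r is None:
        return None
    if p + r == 0:
        return None
    return 2.0 * p * r / (p + r)


def rmse(predictions, truths) -> float:
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.shape != truths.shape:
        raise ValueError("predictions and truths must have equal shape")
    if predictions.size == 0:
        raise ValueError("rmse undefined for empty input")
    return float(np.sqrt(np.mean((predictions - truths) ** 2)))


def r_squared(predictions, truths) -> float:
    """Coefficient of determination of predictions against truths."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    ss_res = float(np.sum((truths - predictions) ** 2))
    ss_tot = float(np.sum((truths - truths.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("r_squared undefined for constant truths")
    return 1.0 - ss_res / ss_tot


def macro_metrics(
    predictions, truths, classes: Sequence | None = None, spec_mode: str = "standard"
) -> dict:
    """Macro-averaged one-vs-rest metrics over all classes.

    Per-class undefined values are dropped from each macro average.
    ``accuracy`` is the plain multiclass accuracy (fraction of exact
    label matches), not an average of one-vs-rest accuracies.
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    if classes is None:
        classes = np.unique(np.concatenate([truths, predictions]))
    per_class = {}
    for cls in classes:
        c = confusion_counts(predictions, truths, cls)
        per_class[cls] = {
            "sensitivity": sensitivity(c),
            "specificity_standard": specificity(c, "standard"),
            "specificity_paper": specificity(c, "paper"),
            "precision": precision(c),
            "f_measure": f_measure(c),
        }
    out: dict = {"accuracy": float(np.mean(predictions == truths))}
    for key in (
        "sensitivity",
        "specificity_standard",
        "specificity_paper",
        "precision",
        "f_measure",
    ):
        vals = [m[key] for m in per_class.values() if m[key] is not None]
        out[key] = float(np.mean(vals)) if vals else None
    out["per_class"] = per_class
    return out


def kfold_split(
    n: int, k: int, seed: int = 0, labels: Sequence | None = None
) -> FoldAssignment:
    """Stratified k-fold assignment; fold sizes differ by at most one.

    Training uses k-1 folds and validation the held-out one (the
    conventional scheme).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds sample count n={n}")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(n, dtype=int)
    if labels is None:
        order = rng.permutation(n)
        fold_of[order] = np.arange(n) % k
    else:
        labels = np.asarray(labels)
        if len(labels) != n:
            raise ValueError("labels length must equal n")
        offset = 0  # stagger classes so global fold sizes stay balanced
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            order = rng.permutation(len(idx))
            fold_of[idx[order]] = (np.arange(len(idx)) + offset) % k
            offset += len(idx)
    return FoldAssignment(k=k, fold_of=fold_of)


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    train_and_predict,
    k: int = 10,
    seed: int = 0,
    labels: Sequence | None = None,
    task_kind: str = "classification",
) -> MetricsReport:
    """k-fold cross-validation around a caller-supplied training routine.

    ``train_and_predict(x_train, y_train, x_val, fold)`` must return
    predictions for ``x_val``.  Classification folds report the macro
    metrics; regression folds report RMSE.  A fold that raises is marked
    failed and excluded from the mean.
    """
    if labels is None and task_kind == "classification":
        labels = y
    assignment = kfold_split(len(x), k, seed=seed, labels=labels)
    report = MetricsReport()
    for fold in range(k):
        train_idx, val_idx = assignment.indices(fold)
        try:
            preds = train_and_predict(x[train_idx], y[train_idx], x[val_idx], fold)
        except Exception as exc:  # noqa: BLE001 - fold failure is reported, not fatal
            warnings.warn(f"fold {fold} failed: {exc}", stacklevel=2)
            report.folds.append({"failed": 1.0})
            continue
        if task_kind == "classification":
            row = {
                k_: v
                for k_, v in macro_metrics(preds, y[val_idx]).items()
                if k_ != "per_class"
            }
        else:
            row = {"rmse": rmse(preds, y[val_idx])}
        row["failed"] = None
        report.folds.append(row)
    return report
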