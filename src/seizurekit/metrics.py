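"""Confusion counts, derived metrics, cross-validation, and outlier filtering.

All derived metrics are reported on the percent scale:

* accuracy      = (TP+TN)/(TP+FP+TN+FN) × 100
* sensitivity   = recall = TP/(TP+FN) × 100
* specificity   = TN/(TN+FP) × 100
* positive_predictivity = precision = TP/(TP+FP) × 100
* f1            = 2·precision·recall/(precision+recall)
* fall_out      = FP/(TN+FP) × 100  (complement of specificity)
* miss_rate     = FN/(TP+FN) × 100  (complement of sensitivity)

"Seizure" (``State == "s"``) is the positive class. A metric whose
denominator is zero is reported as ``nan`` ("undefined") with a logged
warning, never as 0.

Cross-validation is stratified K-fold (K = 5 by default, seeded,
reproducible); K equal to the number of rows degrades gracefully to
leave-one-out. Per-fold confusion counts are pooled by summation before
metrics are derived, so the pooled report reflects every sample exactly
once.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classify import predict, train
from .features import FEATURE_COLUMNS, STATE_COLUMN, STATE_NORMAL, STATE_SEIZURE

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "FoldAssignment",
    "CrossValidationResult",
    "confusion",
    "compute_metrics",
    "kfold_assign",
    "cross_validate",
    "filter_abnormal",
    "format_report_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.tn + other.tn,
            self.fp + other.fp, self.fn + other.fn,
        )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MetricsReport:
    """The nine derived metrics, percent scale; undefined entries are nan."""

    accuracy: float
    sensitivity: float
    specificity: float
    positive_predictivity: float
    recall: float
    precision: float
    f1: float
    fall_out: float
    miss_rate: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {k: (None if math.isnan(v) else v) for k, v in self.to_dict().items()},
            **kwargs,
        )


def confusion(y_true, y_pred, positive: str = STATE_SEIZURE) -> ConfusionCounts:
    """Count TP/TN/FP/FN with seizure as the positive class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"label length mismatch: {y_true.shape} vs {y_pred.shape}"
        )
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if len(labels - {positive}) > 1:
        raise ValueError(f"labels must be binary, got {sorted(map(str, labels))}")
    t = y_true == positive
    p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reported as nan", name)
        return float("nan")
    return 100.0 * num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive the nine percent-scale metrics from confusion counts."""
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    accuracy = _ratio(c.tp + c.tn, c.total, "accuracy")
    if math.isnan(precision) or math.isnan(sensitivity) or precision + sensitivity == 0:
        logger.warning("f1 undefined; reported as nan")
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricsReport(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        positive_predictivity=precision,
        recall=sensitivity,
        precision=precision,
        f1=f1,
        fall_out=100.0 - specificity if not math.isnan(specificity) else float("nan"),
        miss_rate=100.0 - sensitivity if not math.isnan(sensitivity) else float("nan"),
    )


@dataclass
class FoldAssignment:
    """Fold index per row of a feature table."""

    fold_index: np.ndarray
    K: int
    seed: int


def kfold_assign(table: pd.DataFrame, K: int = 5, seed: int = 0) -> FoldAssignment:
    """Stratified, seeded K-fold assignment (K = number of rows → LOOCV)."""
    n = len(table)
    if K < 2:
        raise ValueError("K must be >= 2")
    y = table[STATE_COLUMN].to_numpy()
    fold_index = np.empty(n, dtype=int)
    if K == n:  # leave-one-out: one row per fold, stratification is vacuous
        fold_index[:] = np.random.default_rng(seed).permutation(n)
        return FoldAssignment(fold_index=fold_index, K=K, seed=seed)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < K:
        raise ValueError(
            f"smallest class has {counts.min()} rows; stratified {K}-fold "
            "needs at least K rows per class"
        )
    splitter = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), y)):
        fold_index[test_idx] = fold
    return FoldAssignment(fold_index=fold_index, K=K, seed=seed)


@dataclass
class CrossValidationResult:
    pooled: MetricsReport
    pooled_counts: ConfusionCounts
    fold_reports: list[MetricsReport]
    fold_counts: list[ConfusionCounts]
    assignment: FoldAssignment
    classifier: str

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "K": self.assignment.K,
            "seed": self.assignment.seed,
            "pooled_counts": self.pooled_counts.to_dict(),
            "pooled_metrics": self.pooled.to_dict(),
            "fold_counts": [c.to_dict() for c in self.fold_counts],
            "fold_metrics": [r.to_dict() for r in self.fold_reports],
        }


def cross_validate(
    name: str, table: pd.DataFrame, K: int = 5, seed: int = 0, **hyperparameters
) -> CrossValidationResult:
    """K-fold cross-validation of one classifier on a feature table.

    Per fold: fit on the other K−1 folds, predict the held-out fold. The
    pooled confusion is the sum of per-fold confusions.
    """
    assignment = kfold_assign(table, K=K, seed=seed)
    table = table.reset_index(drop=True)
    fold_counts: list[ConfusionCounts] = []
    fold_reports: list[MetricsReport] = []
    for fold in range(K):
        held = assignment.fold_index == fold
        model = train(name, table.loc[~held], seed=seed, **hyperparameters)
        y_pred = predict(model, table.loc[held])
        counts = confusion(table.loc[held, STATE_COLUMN].to_numpy(), y_pred)
        fold_counts.append(counts)
        fold_reports.append(compute_metrics(counts))
    pooled_counts = sum(fold_counts[1:], fold_counts[0])
    return CrossValidationResult(
        pooled=compute_metrics(pooled_counts),
        pooled_counts=pooled_counts,
        fold_reports=fold_reports,
        fold_counts=fold_counts,
        assignment=assignment,
        classifier=name,
    )


def filter_abnormal(
    table: pd.DataFrame, z_threshold: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop training rows that sit deep inside the opposite class's cluster.

    Features are first passed through ``asinh`` — linear near zero,
    logarithmic at large amplitude — so the heavy-tailed amplitude features
    (Var, MOM, POW span many decades) do not dominate. On that scale, a
    robust z-score per column is computed against the row's own class
    (median center, 1.4826·MAD scale); columns are oriented by the sign of
    (seizure median − normal median) so that "positive" always means
    "toward the seizure side". A row's score is the mean oriented z over the
    usable columns. Normal rows scoring above ``z_threshold`` (seizure-like)
    and seizure rows scoring below ``−z_threshold`` (normal-like) are
    removed. Returns ``(filtered_table, removed_rows)``; the removed-rows
    frame carries the offending score in an ``abnormality_z`` column.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    y = table[STATE_COLUMN].to_numpy()
    for cls in (STATE_SEIZURE, STATE_NORMAL):
        if int(np.sum(y == cls)) < 3:
            raise ValueError(f"need >= 3 rows of class {cls!r} to filter")
    X = np.arcsinh(table[FEATURE_COLUMNS].to_numpy(dtype=float))
    med = {c: np.median(X[y == c], axis=0) for c in (STATE_SEIZURE, STATE_NORMAL)}
    mad = {
        c: 1.4826 * np.median(np.abs(X[y == c] - med[c]), axis=0)
        for c in (STATE_SEIZURE, STATE_NORMAL)
    }
    direction = np.sign(med[STATE_SEIZURE] - med[STATE_NORMAL])
    direction[direction == 0] = 1.0
    scores = np.zeros(len(table))
    for c in (STATE_SEIZURE, STATE_NORMAL):
        rows = y == c
        usable = mad[c] > 0
        if not usable.any():
            continue
        z = (X[np.ix_(rows, usable)] - med[c][usable]) / mad[c][usable]
        scores[rows] = np.mean(z * direction[usable], axis=1)
    drop = ((y == STATE_NORMAL) & (scores > z_threshold)) | (
        (y == STATE_SEIZURE) & (scores < -z_threshold)
    )
    removed = table.loc[drop].copy()
    removed["abnormality_z"] = scores[drop]
    return table.loc[~drop].copy(), removed


def format_report_table(reports: dict[str, tuple[ConfusionCounts, MetricsReport]]) -> str:
    """Text table of counts + metrics, one column per classifier."""
    rows = ["TP", "TN", "FP", "FN", "Accuracy", "Sensitivity", "Specificity",
            "PositivePre", "F1", "FallOut", "MisRate"]
    getters = {
        "TP": lambda c, r: f"{c.tp}", "TN": lambda c, r: f"{c.tn}",
        "FP": lambda c, r: f"{c.fp}", "FN": lambda c, r: f"{c.fn}",
        "Accuracy": lambda c, r: f"{r.accuracy:.5f}",
        "Sensitivity": lambda c, r: f"{r.sensitivity:.5f}",
        "Specificity": lambda c, r: f"{r.specificity:.5f}",
        "PositivePre": lambda c, r: f"{r.positive_predictivity:.5f}",
        "F1": lambda c, r: f"{r.f1:.5f}",
        "FallOut": lambda c, r: f"{r.fall_out:.5f}",
        "MisRate": lambda c, r: f"{r.miss_rate:.5f}",
    }
    names = list(reports)
    width = max(12, *(len(n) + 2 for n in names))
    lines = ["".ljust(12) + "".join(n.rjust(width) for n in names)]
    for row in rows:
        cells = [getters[row](*reports[n]) for n in names]
        lines.append(row.ljust(12) + "".join(c.rjust(width) for c in cells))
    return "\n".join(lines)
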