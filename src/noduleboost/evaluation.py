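"""Binary-classification evaluation: confusion counts, the derived rates,
ROC/AUC, and the data-splitting harnesses (80/20 hold-out, stratified
10-fold cross-validation).

The nodule class (+1) is the positive class throughout:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)          (recall on nodules)
    specificity = TN / (TN + FP)          (recall on nonnodules)
    TPR = TP / (TP + FN),  FPR = FP / (TN + FP)

The ROC curve sweeps a threshold over the continuous score (for an
ensemble, the voting margin) from high to low; AUC is the trapezoidal area,
which for a grouped-ties sweep equals the Mann-Whitney probability that a
random positive outscores a random negative (ties counted half).

Metrics with an empty denominator raise ``UndefinedMetricError`` instead of
silently returning 0 — silent zeros would corrupt fold averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "UndefinedMetricError",
    "confusion",
    "metrics",
    "RocCurve",
    "roc",
    "split_80_20",
    "stratified_kfold",
    "cross_validate_kfold",
]


class UndefinedMetricError(ZeroDivisionError):
    """A requested rate has an empty denominator."""


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_pm1(v, name):
    v = np.asarray(v)
    if not np.all(np.isin(v, (-1, 1))):
        raise ValueError(f"{name} must be ±1 valued")
    return v


def confusion(pred_labels: np.ndarray, true_labels: np.ndarray) -> ConfusionMatrix:
    """Tally the 2×2 table with +1 = nodule = positive."""
    pred = _check_pm1(pred_labels, "pred_labels")
    true = _check_pm1(true_labels, "true_labels")
    if len(pred) != len(true):
        raise ValueError(f"length mismatch: {len(pred)} predictions, {len(true)} labels")
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (true == 1))),
        tn=int(np.sum((pred == -1) & (true == -1))),
        fp=int(np.sum((pred == 1) & (true == -1))),
        fn=int(np.sum((pred == -1) & (true == 1))),
    )


def metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) as exact ratios.

    Raises UndefinedMetricError when a denominator is zero (no samples, no
    positives, or no negatives respectively).
    """
    if cm.n == 0:
        raise UndefinedMetricError("no samples: accuracy undefined")
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("no positive samples: sensitivity undefined")
    if cm.tn + cm.fp == 0:
        raise UndefinedMetricError("no negative samples: specificity undefined")
    accuracy = (cm.tp + cm.tn) / cm.n
    sensitivity = cm.tp / (cm.tp + cm.fn)
    specificity = cm.tn / (cm.tn + cm.fp)
    return accuracy, sensitivity, specificity


@dataclass(frozen=True)
class RocCurve:
    """Threshold sweep of (FPR, TPR) plus the trapezoidal AUC."""

    points: np.ndarray  # (k, 2) array of (fpr, tpr), fpr non-decreasing
    auc: float
    thresholds: np.ndarray  # cutoff generating each point (inf for (0,0))


def roc(margin_scores: np.ndarray, true_labels: np.ndarray) -> RocCurve:
    """ROC curve from continuous scores; predict +1 where score >= cutoff.

    Thresholds sweep the unique scores in descending order (one point per
    unique value, so ties are grouped); (0,0) is prepended and — when the
    lowest threshold does not already reach it — (1,1) appended.  AUC is the
    trapezoidal area, equal to the Mann-Whitney statistic
    P(score+ > score-) + 0.5 P(tie).
    """
    scores = np.asarray(margin_scores, dtype=np.float64)
    labels = _check_pm1(true_labels, "true_labels")
    if len(scores) != len(labels):
        raise ValueError("scores and labels must share a length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")

    cuts = np.unique(scores)[::-1]
    fpr = [0.0]
    tpr = [0.0]
    thresholds = [np.inf]
    for t in cuts:
        pred_pos = scores >= t
        tpr.append(np.sum(pred_pos & (labels == 1)) / n_pos)
        fpr.append(np.sum(pred_pos & (labels == -1)) / n_neg)
        thresholds.append(t)
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
        thresholds.append(-np.inf)
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocCurve(points=points, auc=auc, thresholds=np.array(thresholds))


# ---------------------------------------------------------------------------
# splits


def split_80_20(
    labels: np.ndarray, seed: int = 0, test_fraction: float = 0.2
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified hold-out split; returns (train indices, test indices).

    |test| = round(test_fraction * n), apportioned over classes by largest
    remainder so the stratification is as even as the counts allow; falls
    back to an unstratified split (with a warning) when a class has fewer
    than 2 members.  Deterministic per seed.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    n_test = int(round(test_fraction * n))
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        import warnings

        warnings.warn("a class has < 2 members; falling back to unstratified split",
                      stacklevel=2)
        order = rng.permutation(n)
        return np.sort(order[n_test:]), np.sort(order[:n_test])

    # largest-remainder apportionment of the test quota across classes
    quotas = counts * n_test / n
    base = np.floor(quotas).astype(int)
    remainder_order = np.argsort(-(quotas - base))
    for i in range(n_test - base.sum()):
        base[remainder_order[i % len(classes)]] += 1
    test_idx = []
    for cls, take in zip(classes, base):
        members = np.flatnonzero(labels == cls)
        members = members[rng.permutation(len(members))]
        test_idx.extend(members[:take])
    test = np.sort(np.array(test_idx, dtype=int))
    train = np.setdiff1d(np.arange(n), test)
    return train, test


def stratified_kfold(
    labels: np.ndarray, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """k stratified folds (lists of test indices), sizes differing by <= 1.

    Each class is shuffled then dealt round-robin to folds, starting at a
    rotating offset so fold sizes balance across classes.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(
            f"cannot make {k} folds from {n} samples; reduce k in the config"
        )
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    offset = 0
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        members = members[rng.permutation(len(members))]
        for i, idx in enumerate(members):
            folds[(offset + i) % k].append(int(idx))
        offset += len(members)
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate_kfold(
    x: np.ndarray,
    labels: np.ndarray,
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    k: int = 10,
    seed: int = 0,
) -> dict:
    """Stratified k-fold harness.

    ``fit_predict(x_train, y_train, x_test)`` must return (hard ±1 labels,
    continuous scores) for the test fold.  Every fold must contain both
    classes.  Returns per-fold accuracy/sensitivity/specificity/AUC and
    their means.
    """
    labels = _check_pm1(labels, "labels")
    folds = stratified_kfold(labels, k=k, seed=seed)
    per_fold = []
    all_idx = np.arange(len(labels))
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        hard, scores = fit_predict(x[train_idx], labels[train_idx], x[test_idx])
        cm = confusion(hard, labels[test_idx])
        acc, sens, spec = metrics(cm)
        auc = roc(scores, labels[test_idx]).auc
        per_fold.append(
            {"fold": f, "accuracy": acc, "sensitivity": sens,
             "specificity": spec, "auc": auc}
        )
    mean = {
        key: float(np.mean([p[key] for p in per_fold]))
        for key in ("accuracy", "sensitivity", "specificity", "auc")
    }
    return {"folds": per_fold, "mean": mean}
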