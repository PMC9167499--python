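"""Cross-validation protocol and ROC/AUC metrics.

The evaluation design is 10-fold cross-validation with rotating roles: the
dataset is split into ten parts; fold i is the test set, the next fold
(cyclically) is the validation set used for early stopping, and the
remaining eight folds form the training set.  Every record is therefore
tested exactly once and never leaks into its own training set.  AUC is the
headline metric.

ROC and AUC are computed with scikit-learn; the test suite checks the
trapezoidal AUC against a brute-force Mann–Whitney concordance count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index (0..k-1) per record; a disjoint exhaustive partition."""

    fold_of: np.ndarray
    k: int
    stratified: bool
    seed: int

    def indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


@dataclass
class CrossValidationResult:
    fold_aucs: list[float]
    mean_auc: float
    folds: FoldAssignment
    fold_details: list[dict] = field(default_factory=list)


def make_kfold(labels: list[int] | np.ndarray, k: int = 10,
               stratified: bool = True, seed: int = 0) -> FoldAssignment:
    """Assign each record to one of ``k`` folds (shuffled, optionally
    stratified so class ratios are preserved per fold within rounding)."""
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError(f"cannot split {n} records into {k} folds")
    splitter = (StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
                if stratified else
                KFold(n_splits=k, shuffle=True, random_state=seed))
    fold_of = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(n), labels)):
        fold_of[test_idx] = fold
    return FoldAssignment(fold_of=fold_of, k=k, stratified=stratified, seed=seed)


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and trapezoidal AUC; ties receive half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = set(labels.tolist())
    if classes != {0, 1}:
        raise ValueError(f"AUC needs both classes present, got labels {classes}")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr,
                     auc=float(_trapezoid_auc(fpr, tpr)))


def cross_validate(dataset: list, model_builder, k: int = 10, seed: int = 0,
                   stratified: bool = True) -> CrossValidationResult:
    """Rotating k-fold cross-validation.

    ``model_builder(train_records, val_records, fold_seed)`` must return an
    object with ``predict_scores(records) -> array``.  For fold i the test
    set is fold i, the validation set fold (i+1) mod k, and the training
    set the remaining k-2 folds.
    """
    labels = np.array([r.label for r in dataset])
    folds = make_kfold(labels, k=k, stratified=stratified, seed=seed)
    fold_aucs: list[float] = []
    details: list[dict] = []
    for i in range(k):
        test_idx = folds.indices(i)
        val_idx = folds.indices((i + 1) % k)
        train_mask = ~np.isin(folds.fold_of, [i, (i + 1) % k])
        train = [dataset[j] for j in np.flatnonzero(train_mask)]
        val = [dataset[j] for j in val_idx]
        test = [dataset[j] for j in test_idx]
        try:
            model = model_builder(train, val, seed + i)
            scores = model.predict_scores(test)
        except Exception as exc:
            raise RuntimeError(f"fold {i} failed: {exc}") from exc
        fold_auc = roc_auc(scores, labels[test_idx]).auc
        fold_aucs.append(fold_auc)
        details.append({"fold": i, "n_train": len(train), "n_val": len(val),
                        "n_test": len(test), "auc": fold_auc})
    return CrossValidationResult(fold_aucs=fold_aucs,
                                 mean_auc=float(np.mean(fold_aucs)),
                                 folds=folds, fold_details=details)
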