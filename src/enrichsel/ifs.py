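"""Incremental feature selection with an SMO-family SVM scored by MCC.

For a ranked feature list, every prefix F^i (the first i features) is
evaluated by stratified 10-fold cross-validation of a soft-margin SVM;
predictions are pooled across folds into one confusion matrix, from which
accuracy, specificity, sensitivity, and Matthews's correlation coefficient
are computed:

    ACC = (TP + TN) / (TP + TN + FP + FN)
    SP  = TN / (TN + FP)
    SN  = TP / (TP + FN)
    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP))

The optimal feature set is the smallest prefix attaining the maximum MCC
along the curve. Features are standardized inside each training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .datasets import NEGATIVE_LABEL, POSITIVE_LABEL
from .types import FeatureMatrix, RankedFeatureLists, RunConfig, TermId


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    acc: float
    sp: float
    sn: float
    mcc: float


def metrics_from_confusion(c: ConfusionCounts) -> MetricSet:
    """ACC/SP/SN/MCC from pooled confusion counts (0 when a denominator is 0)."""
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    total = c.total
    acc = (tp + tn) / total if total else 0.0
    sp = tn / (tn + fp) if (tn + fp) else 0.0
    sn = tp / (tp + fn) if (tp + fn) else 0.0
    denom = sqrt(float(tn + fn) * (tn + fp) * (tp + fn) * (tp + fp))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return MetricSet(acc=acc, sp=sp, sn=sn, mcc=mcc)


def _make_svc(config: RunConfig) -> SVC:
    kernel = config.svm_kernel.lower()
    if kernel in ("polynomial", "poly"):
        kernel = "linear" if config.svm_degree == 1 else "poly"
    elif kernel in ("gaussian", "rbf"):
        kernel = "rbf"
    elif kernel != "linear":
        raise ValueError(f"unsupported kernel {config.svm_kernel!r}")
    return SVC(
        kernel=kernel,
        C=config.svm_c,
        degree=config.svm_degree,
        gamma=config.svm_gamma,
    )


def _fold_indices(y: np.ndarray, folds: int, seed: int):
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros((len(y), 1)), y))


def _standardize(train: np.ndarray, test: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (train - mu) / sd, (test - mu) / sd


def _pooled_confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    pos = y_true == POSITIVE_LABEL
    neg = y_true == NEGATIVE_LABEL
    return ConfusionCounts(
        tp=int(np.count_nonzero(pos & (y_pred == POSITIVE_LABEL))),
        tn=int(np.count_nonzero(neg & (y_pred == NEGATIVE_LABEL))),
        fp=int(np.count_nonzero(neg & (y_pred == POSITIVE_LABEL))),
        fn=int(np.count_nonzero(pos & (y_pred == NEGATIVE_LABEL))),
    )


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    config: Optional[RunConfig] = None,
) -> ConfusionCounts:
    """Stratified k-fold CV of the SVM; returns pooled confusion counts.

    Each sample is tested exactly once. Standardization statistics come
    from the training folds only.
    """
    config = config or RunConfig(cv_folds=folds, seed=seed)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present for cross-validation")
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} samples per class for {folds}-fold "
            f"stratified CV, smallest class has {counts.min()}"
        )
    y_pred = np.empty_like(y)
    for train_idx, test_idx in _fold_indices(y, folds, seed):
        Xtr, Xte = _standardize(X[train_idx], X[test_idx])
        clf = _make_svc(config).fit(Xtr, y[train_idx])
        y_pred[test_idx] = clf.predict(Xte)
    return _pooled_confusion(y, y_pred)


def train_classifier(X: np.ndarray, y: np.ndarray, config: Optional[RunConfig] = None):
    """Fit the SVM on standardized features; returns (classifier, scaler fn)."""
    config = config or RunConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    mu = X.mean(axis=0)
    sd = np.where(X.std(axis=0) == 0.0, 1.0, X.std(axis=0))
    clf = _make_svc(config).fit((X - mu) / sd, y)

    def predict(Xnew: np.ndarray) -> np.ndarray:
        return clf.predict((np.asarray(Xnew, dtype=float) - mu) / sd)

    return clf, predict


@dataclass
class IFSResult:
    """IFS curve plus the extracted maximum-MCC optimal feature set."""

    curve: List[Tuple[int, MetricSet]]
    optimal_size: int
    optimal_features: List[TermId]
    max_mcc: float

    @property
    def mccs(self) -> List[float]:
        return [m.mcc for _, m in self.curve]


def optimal_prefix(mccs: Sequence[float]) -> int:
    """Smallest prefix length attaining the maximum MCC (1-based)."""
    if not mccs:
        raise ValueError("empty IFS curve")
    best = max(mccs)
    return next(i for i, v in enumerate(mccs, start=1) if v == best)


class IncrementalFeatureSelector(BaseEstimator):
    """Evaluate growing prefixes of pre-ranked features with CV'd SVM + MCC.

    Expects ``X`` columns already ordered by the ranking stage (mRMR order).

    Parameters
    ----------
    cv : int, default=10
        Number of stratified folds.
    config : RunConfig, optional
        SVM kernel/C and fold settings.
    random_state : int, default=0
        Seed for the fold assignment.

    Attributes
    ----------
    curve_ : list of (prefix size, MetricSet)
    optimal_size_ : int
        Smallest prefix with maximal MCC.
    max_mcc_ : float
    support_ : ndarray of bool
        Mask over input columns selecting the optimal prefix.
    """

    def __init__(
        self,
        cv: int = 10,
        config: Optional[RunConfig] = None,
        random_state: int = 0,
    ) -> None:
        self.cv = cv
        self.config = config
        self.random_state = random_state

    def fit(self, X, y) -> "IncrementalFeatureSelector":
        config = self.config or RunConfig(cv_folds=self.cv)
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] == 0:
            raise ValueError("X must be 2-D with at least one ranked feature")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2 or counts.min() < self.cv:
            raise ValueError("each class needs at least `cv` samples")
        folds = _fold_indices(y, self.cv, self.random_state)
        # standardize the full matrix once per fold; prefixes are column slices
        scaled = []
        for train_idx, test_idx in folds:
            Xtr, Xte = _standardize(X[train_idx], X[test_idx])
            scaled.append((train_idx, test_idx, Xtr, Xte))
        self.curve_ = []
        for i in range(1, X.shape[1] + 1):
            y_pred = np.empty_like(y)
            for train_idx, test_idx, Xtr, Xte in scaled:
                clf = _make_svc(config).fit(Xtr[:, :i], y[train_idx])
                y_pred[test_idx] = clf.predict(Xte[:, :i])
            self.curve_.append((i, metrics_from_confusion(_pooled_confusion(y, y_pred))))
        mccs = [m.mcc for _, m in self.curve_]
        self.optimal_size_ = optimal_prefix(mccs)
        self.max_mcc_ = max(mccs)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[: self.optimal_size_] = True
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X)[:, self.support_]


def run_ifs(
    matrix: FeatureMatrix,
    ranked: RankedFeatureLists,
    config: Optional[RunConfig] = None,
    seed: int = 0,
) -> IFSResult:
    """Run IFS over the mRMR list of a labeled feature matrix."""
    config = config or RunConfig()
    if matrix.labels is None:
        raise ValueError("feature matrix must carry binary labels")
    if not ranked.mrmr:
        raise ValueError("empty mRMR list")
    ordered = matrix.subset_features(ranked.mrmr)
    selector = IncrementalFeatureSelector(
        cv=config.cv_folds, config=config, random_state=seed
    ).fit(ordered.values, matrix.labels)
    return IFSResult(
        curve=selector.curve_,
        optimal_size=selector.optimal_size_,
        optimal_features=list(ranked.mrmr[: selector.optimal_size_]),
        max_mcc=selector.max_mcc_,
    )
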