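"""Stage-1 feature filtering by Cramér's coefficient with the class label.

Continuous enrichment scores are discretized (default: three states split at
mean +/- one standard deviation, computed per dataset), tabulated against the
binary label, and scored with Cramér's V = sqrt(chi2 / (n (min(r, c) - 1))).
Features with V below the threshold (default 0.1) are excluded; V equal to
the threshold is kept (strict-less exclusion).
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted

from .types import FeatureMatrix, TermId

THREE_STATE = "three_state_mean_sd"
ZERO_VS_POSITIVE = "zero_vs_positive"
SCHEMES = (THREE_STATE, ZERO_VS_POSITIVE)


def discretize_feature(values: np.ndarray, scheme: str = THREE_STATE) -> np.ndarray:
    """Map a real-valued feature to integer bins.

    three_state_mean_sd: bins (-inf, mu-sigma], (mu-sigma, mu+sigma),
    [mu+sigma, inf) -> {0, 1, 2}; a constant feature (sigma = 0) maps
    entirely to the middle bin. zero_vs_positive: {0} vs (0, inf) -> {0, 1},
    suited to zero-inflated enrichment scores.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("expected a non-empty 1-D value vector")
    if scheme == ZERO_VS_POSITIVE:
        return (values > 0).astype(int)
    if scheme != THREE_STATE:
        raise ValueError(f"unknown discretization scheme {scheme!r}")
    mu, sigma = values.mean(), values.std()
    if sigma == 0.0:
        return np.ones(values.shape, dtype=int)
    bins = np.ones(values.shape, dtype=int)
    bins[values <= mu - sigma] = 0
    bins[values >= mu + sigma] = 2
    return bins


def discretize_matrix(X: np.ndarray, scheme: str = THREE_STATE) -> np.ndarray:
    """Column-wise discretization of a samples x features matrix."""
    X = np.asarray(X, dtype=float)
    if scheme == ZERO_VS_POSITIVE:
        return (X > 0).astype(int)
    if scheme != THREE_STATE:
        raise ValueError(f"unknown discretization scheme {scheme!r}")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    lo = mu - sigma
    hi = mu + sigma
    bins = np.ones(X.shape, dtype=int)
    np.putmask(bins, X <= lo, 0)
    np.putmask(bins, X >= hi, 2)
    bins[:, sigma == 0.0] = 1
    return bins


def cramers_v(table: np.ndarray) -> float:
    """Cramér's V of an r x c contingency table (no continuity correction).

    Rows and columns with zero marginals are dropped first; degenerate
    tables (fewer than two non-empty rows or columns) score 0.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or np.any(table < 0):
        raise ValueError("table must be a 2-D non-negative count matrix")
    n = table.sum()
    if n < 1:
        raise ValueError("table must contain at least one count")
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    r, c = table.shape
    if r < 2 or c < 2:
        return 0.0
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    chi2 = ((table - expected) ** 2 / expected).sum()
    v = np.sqrt(chi2 / (n * (min(r, c) - 1)))
    return float(min(v, 1.0))


def _label_association(Xd: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Cramér's V of each discretized column against the binary label."""
    n, p = Xd.shape
    out = np.empty(p, dtype=float)
    classes = np.unique(y)
    for j in range(p):
        states = np.unique(Xd[:, j])
        table = np.zeros((states.size, classes.size))
        for a, s in enumerate(states):
            for b, cls in enumerate(classes):
                table[a, b] = np.count_nonzero((Xd[:, j] == s) & (y == cls))
        out[j] = cramers_v(table)
    return out


class CramerFilter(SelectorMixin, BaseEstimator):
    """Select features whose Cramér's V with the label reaches a threshold.

    Parameters
    ----------
    threshold : float, default=0.1
        Features with V strictly below this are excluded.
    scheme : str, default="three_state_mean_sd"
        Discretization applied to each feature before tabulation.

    Attributes
    ----------
    scores_ : ndarray of shape (n_features,)
        Per-feature Cramér's V values.
    """

    def __init__(self, threshold: float = 0.1, scheme: str = THREE_STATE) -> None:
        self.threshold = threshold
        self.scheme = scheme

    def fit(self, X, y) -> "CramerFilter":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        self.n_features_in_ = X.shape[1]
        Xd = discretize_matrix(X, self.scheme)
        self.scores_ = _label_association(Xd, y)
        return self

    def _get_support_mask(self) -> np.ndarray:
        check_is_fitted(self, "scores_")
        return self.scores_ >= self.threshold


def filter_features(
    matrix: FeatureMatrix,
    threshold: float = 0.1,
    scheme: str = THREE_STATE,
) -> Tuple[List[TermId], Dict[TermId, float]]:
    """Apply the Cramér filter to a labeled feature matrix.

    Returns the surviving terms in original feature order and the full
    per-term V map for auditing.
    """
    if matrix.labels is None:
        raise ValueError("feature matrix must carry binary labels")
    selector = CramerFilter(threshold=threshold, scheme=scheme).fit(
        matrix.values, matrix.labels
    )
    mask = selector.get_support()
    survivors = [t for t, keep in zip(matrix.features, mask) if keep]
    values = dict(zip(matrix.features, selector.scores_.tolist()))
    return survivors, values
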