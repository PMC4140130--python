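"""Stage-2 ranking: MaxRel and greedy mRMR (MID) feature lists.

Relevance is the plug-in mutual information (in bits) between a discretized
feature and the class label. MaxRel sorts features by relevance alone; mRMR
selects greedily with the mutual-information-difference (MID) criterion

    score(f) = I(f; y) - (1 / |S|) * sum_{s in S} I(f; s)

seeding with the most relevant feature. Ties break toward the earlier
feature in term order, making runs reproducible. Both lists are truncated
to the top ``k`` (default 500) features.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .cramer import THREE_STATE, discretize_matrix
from .types import FeatureMatrix, RankedFeatureLists, TermId


def mutual_information(x: Sequence[int], y: Sequence[int]) -> float:
    """Plug-in estimate of I(X; Y) in bits for two discrete vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    nx, ny = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ny + yi, minlength=nx * ny).reshape(nx, ny)
    return _mi_from_counts(joint)


def _mi_from_counts(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _mi_one_vs_many(s: np.ndarray, Xd: np.ndarray, n_states: int) -> np.ndarray:
    """I(s; column) for every column of Xd, vectorized via joint bincounts."""
    n, p = Xd.shape
    codes = s[:, None] * n_states + Xd  # (n, p) joint cell codes
    offsets = np.arange(p) * (n_states * n_states)
    flat = np.bincount(
        (codes + offsets).ravel(), minlength=p * n_states * n_states
    ).reshape(p, n_states, n_states)
    pj = flat / n
    pa = pj.sum(axis=2, keepdims=True)
    pb = pj.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pj * np.log2(pj / (pa * pb))
    return np.nansum(terms, axis=(1, 2))


class MRMRRanker(BaseEstimator):
    """Rank features by max-relevance and by greedy min-redundancy (MID).

    Parameters
    ----------
    k : int, default=500
        Length cap on both output lists.
    scheme : str, default="three_state_mean_sd"
        Discretization applied to the (continuous) features; the label is
        used as-is.

    Attributes
    ----------
    relevance_ : ndarray of shape (n_features,)
        I(feature; label) in bits per input column.
    maxrel_order_ : ndarray
        Column indices sorted by non-increasing relevance (ties: lower index).
    mrmr_order_ : ndarray
        Column indices in greedy MID selection order.
    """

    def __init__(self, k: int = 500, scheme: str = THREE_STATE) -> None:
        self.k = k
        self.scheme = scheme

    def fit(self, X, y) -> "MRMRRanker":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if X.shape[1] == 0:
            raise ValueError(
                "no surviving features to rank; lower the Cramér threshold"
            )
        self.n_features_in_ = X.shape[1]
        Xd = discretize_matrix(X, self.scheme)
        n_states = int(Xd.max()) + 1
        _, yi = np.unique(y, return_inverse=True)
        n_classes = yi.max() + 1
        states = max(n_states, n_classes + 1)

        relevance = _mi_one_vs_many(yi, Xd, states)
        self.relevance_ = relevance
        # stable sort on negated relevance: ties keep ascending column index
        order = np.argsort(-relevance, kind="stable")
        k = min(self.k, X.shape[1])
        self.maxrel_order_ = order[:k]

        selected = [int(order[0])]
        remaining = [j for j in range(X.shape[1]) if j != selected[0]]
        redundancy_sum = np.zeros(X.shape[1])
        last = selected[0]
        while len(selected) < k and remaining:
            redundancy_sum += _mi_one_vs_many(Xd[:, last], Xd, states)
            scores = relevance[remaining] - redundancy_sum[remaining] / len(selected)
            best = remaining[int(np.argmax(scores))]  # argmax: first max = lowest index
            selected.append(best)
            remaining.remove(best)
            last = best
        self.mrmr_order_ = np.asarray(selected, dtype=int)
        return self

    def transform(self, X) -> np.ndarray:
        """Reorder columns into greedy mRMR order (top-k)."""
        check_is_fitted(self, "mrmr_order_")
        return np.asarray(X)[:, self.mrmr_order_]


def rank_features(
    matrix: FeatureMatrix,
    survivors: Sequence[TermId],
    k: int = 500,
    scheme: str = THREE_STATE,
) -> RankedFeatureLists:
    """Produce MaxRel and mRMR lists over the surviving features.

    ``survivors`` must preserve the matrix's feature order (as produced by
    the Cramér filter), so index tie-breaks coincide with term order.
    """
    if matrix.labels is None:
        raise ValueError("feature matrix must carry binary labels")
    if len(survivors) == 0:
        raise ValueError("no surviving features to rank; lower the Cramér threshold")
    sub = matrix.subset_features(list(survivors))
    ranker = MRMRRanker(k=k, scheme=scheme).fit(sub.values, matrix.labels)
    terms = list(survivors)
    return RankedFeatureLists(
        maxrel=[terms[j] for j in ranker.maxrel_order_],
        mrmr=[terms[j] for j in ranker.mrmr_order_],
        relevance={terms[j]: float(ranker.relevance_[j]) for j in range(len(terms))},
    )
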