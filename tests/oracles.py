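"""Independent brute-force oracles used only by the tests.

These deliberately avoid the implementation's code paths: exact rational
arithmetic for the hypergeometric tail, Counter-based mutual information and
greedy selection for mRMR, and the closed-form 2x2 identity for Cramér's V.
"""

from __future__ import annotations

from collections import Counter
from fractions import Fraction
from math import comb, log2, sqrt
from typing import List, Sequence

import numpy as np


def hypergeom_tail_exact(N: int, M: int, n: int, m: int) -> Fraction:
    """P(X >= m) as an exact rational: sum_k C(M,k) C(N-M,n-k) / C(N,n)."""
    numer = 0
    for k in range(m, n + 1):
        if k > M or n - k > N - M:
            continue
        numer += comb(M, k) * comb(N - M, n - k)
    return Fraction(numer, comb(N, n))


def cramers_v_2x2(a: int, b: int, c: int, d: int) -> float:
    """Closed-form V for a 2x2 table [[a, b], [c, d]]."""
    denom = sqrt((a + b) * (c + d) * (a + c) * (b + d))
    return abs(a * d - b * c) / denom if denom else 0.0


def mi_counter(x: Sequence[int], y: Sequence[int]) -> float:
    """Plug-in mutual information in bits via explicit joint counting."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    total = 0.0
    for (a, b), c in joint.items():
        p_ab = c / n
        total += p_ab * log2(p_ab / ((px[a] / n) * (py[b] / n)))
    return total


def discretize_mean_sd(values: np.ndarray) -> List[int]:
    """Reimplementation of the three-state mean +/- sigma binning."""
    mu = float(np.mean(values))
    sd = float(np.std(values))
    if sd == 0.0:
        return [1] * len(values)
    out = []
    for v in values:
        if v <= mu - sd:
            out.append(0)
        elif v >= mu + sd:
            out.append(2)
        else:
            out.append(1)
    return out


def greedy_mid(X: np.ndarray, y: Sequence[int], k: int) -> List[int]:
    """Brute-force greedy MID selection over pre-discretized columns.

    Relevance I(f; y) minus mean pairwise I(f; s) over selected; ties break
    toward the lowest column index (strict improvement required to switch).
    """
    p = X.shape[1]
    rel = [mi_counter(X[:, j].tolist(), list(y)) for j in range(p)]
    first = max(range(p), key=lambda j: (rel[j], -j))
    selected = [first]
    while len(selected) < min(k, p):
        best_j, best_score = None, None
        for j in range(p):
            if j in selected:
                continue
            red = sum(mi_counter(X[:, j].tolist(), X[:, s].tolist()) for s in selected)
            score = rel[j] - red / len(selected)
            if best_score is None or score > best_score:
                best_j, best_score = j, score
        selected.append(best_j)
    return selected


def metrics_direct(tp: int, tn: int, fp: int, fn: int):
    """Direct spreadsheet-style evaluation of ACC/SP/SN/MCC formulas."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    sn = tp / (tp + fn) if tp + fn else 0.0
    prod = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    mcc = (tp * tn - fp * fn) / sqrt(prod) if prod else 0.0
    return acc, sp, sn, mcc
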