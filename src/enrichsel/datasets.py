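"""Balanced-dataset construction for the imbalanced positive/negative design.

Negatives are drawn uniformly from the universe (ratio x the number of
positives), split randomly into k equal portions, and each portion is joined
with the full positive set to form datasets D_1..D_k. With the reference
design (39 positives, ratio 50, k = 10) every D_i holds 39 positives and 195
negatives, a 5:1 class ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .types import LabeledGeneSet

POSITIVE_LABEL = 1
NEGATIVE_LABEL = 0


@dataclass
class DatasetSplit:
    """Disjoint negative portions and the per-portion datasets D_i = S_p u S_n^i."""

    positives: List[str]
    portions: List[List[str]]
    seed: int

    @property
    def datasets(self) -> List[List[str]]:
        return [list(self.positives) + list(p) for p in self.portions]

    def labels(self, i: int) -> np.ndarray:
        """Binary labels aligned with ``datasets[i]`` (positives first)."""
        return np.array(
            [POSITIVE_LABEL] * len(self.positives)
            + [NEGATIVE_LABEL] * len(self.portions[i]),
            dtype=int,
        )

    @property
    def n_datasets(self) -> int:
        return len(self.portions)


def sample_negatives(
    universe: Sequence[str],
    positives: Sequence[str],
    ratio: int,
    seed: int,
) -> List[str]:
    """Uniform sample of ``ratio * len(positives)`` genes from universe \\ positives."""
    pos = set(positives)
    candidates = [g for g in universe if g not in pos]
    size = ratio * len(positives)
    if len(candidates) < size:
        raise ValueError(
            f"negative universe too small: need {size}, have {len(candidates)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=size, replace=False)
    return [candidates[i] for i in idx]


def split_negatives(
    negatives: Sequence[str],
    positives: Sequence[str],
    k: int,
    seed: int,
) -> DatasetSplit:
    """Randomly permute negatives and deal them round-robin into k portions.

    Portion sizes differ by at most one; the union of portions is exactly the
    negative set and portions are pairwise disjoint.
    """
    if k <= 0:
        raise ValueError("k must be >= 1")
    if len(negatives) < k:
        raise ValueError(f"cannot split {len(negatives)} negatives into {k} portions")
    LabeledGeneSet(list(positives), list(negatives))  # disjointness check
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(negatives))
    portions: List[List[str]] = [[] for _ in range(k)]
    for pos_idx, neg_idx in enumerate(order):
        portions[pos_idx % k].append(negatives[neg_idx])
    return DatasetSplit(positives=list(positives), portions=portions, seed=seed)
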