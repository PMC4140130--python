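"""Aggregation of per-dataset optimal feature sets and category reporting.

The per-dataset optimal sets are unioned into the final optimal feature set;
each member's multiplicity counts how many optimal sets contain it. Category
summaries report, for every child of a namespace root in the term hierarchy,
the frequency |S_o n S(c)| and percentage |S_o n S(c)| / |S(c)| of its
descendant terms present in the final set S_o.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .ifs import IFSResult
from .types import GO, KEGG, TermHierarchy, TermId


@dataclass
class FinalOptimalSet:
    """Union of optimal feature sets with per-term multiplicities."""

    features: frozenset
    multiplicity: Dict[TermId, int]
    n_sets: int

    def __post_init__(self) -> None:
        if set(self.multiplicity) != set(self.features):
            raise ValueError("multiplicity must cover exactly the final features")
        for term, count in self.multiplicity.items():
            if not 1 <= count <= self.n_sets:
                raise ValueError(f"multiplicity of {term.token()} out of range")

    @property
    def by_namespace(self) -> Dict[str, int]:
        counts = Counter(t.namespace for t in self.features)
        return {GO: counts.get(GO, 0), KEGG: counts.get(KEGG, 0)}

    def histogram(self) -> Dict[int, int]:
        """Number of features at each multiplicity value."""
        return dict(sorted(Counter(self.multiplicity.values()).items()))


def combine_optimal_sets(sets: Sequence[Sequence[TermId]]) -> FinalOptimalSet:
    """Union the per-dataset optimal feature sets and count multiplicities."""
    if len(sets) == 0:
        raise ValueError("need at least one optimal feature set")
    multiplicity: Counter = Counter()
    for s in sets:
        multiplicity.update(set(s))
    return FinalOptimalSet(
        features=frozenset(multiplicity),
        multiplicity=dict(multiplicity),
        n_sets=len(sets),
    )


def fraction_shared(final: FinalOptimalSet, min_multiplicity: int) -> float:
    """Fraction of final-set features present in >= min_multiplicity optimal sets."""
    if min_multiplicity < 1:
        raise ValueError("min_multiplicity must be >= 1")
    if not final.features:
        raise ValueError("final optimal set is empty")
    shared = sum(1 for c in final.multiplicity.values() if c >= min_multiplicity)
    return shared / len(final.features)


def category_summary(
    final: FinalOptimalSet, hierarchy: TermHierarchy
) -> pd.DataFrame:
    """Frequency and percentage of final-set terms per root-child category.

    Membership uses descendant closure (all descendants of the category, not
    only direct children); terms under multiple categories count in each.
    Returns a DataFrame sorted by frequency then percentage, descending.
    """
    go_final = {t for t in final.features if t.namespace == GO}
    rows = []
    for cat in hierarchy.category_terms():
        desc = hierarchy.descendants(cat)
        overlap = go_final & desc
        rows.append(
            {
                "category": cat.token(),
                "size": len(desc),
                "frequency": len(overlap),
                "percentage": len(overlap) / len(desc) if desc else 0.0,
            }
        )
    df = pd.DataFrame(rows, columns=["category", "size", "frequency", "percentage"])
    return df.sort_values(
        ["frequency", "percentage", "category"], ascending=[False, False, True]
    ).reset_index(drop=True)


def unmapped_terms(final: FinalOptimalSet, hierarchy: TermHierarchy) -> List[TermId]:
    """GO members of the final set not covered by any category (reported, not fatal)."""
    covered = set()
    for cat in hierarchy.category_terms():
        covered |= hierarchy.descendants(cat)
    return sorted(t for t in final.features if t.namespace == GO and t not in covered)


def summarize_ifs(results: Sequence[IFSResult]) -> pd.DataFrame:
    """Per-dataset optimal sizes and maximum MCCs, with their mean.

    Mirrors the headline table of an IFS study: one row per dataset plus a
    closing mean row over the maximum-MCC column.
    """
    if len(results) == 0:
        raise ValueError("no IFS results to summarize")
    rows = [
        {
            "dataset": f"D{i + 1}",
            "optimal_size": r.optimal_size,
            "max_mcc": r.max_mcc,
        }
        for i, r in enumerate(results)
    ]
    mean_mcc = float(np.mean([r.max_mcc for r in results]))
    rows.append({"dataset": "mean", "optimal_size": np.nan, "max_mcc": mean_mcc})
    return pd.DataFrame(rows, columns=["dataset", "optimal_size", "max_mcc"])


def final_set_table(final: FinalOptimalSet) -> pd.DataFrame:
    """Final optimal set as a (term, namespace, multiplicity) table."""
    rows = [
        {
            "term": t.token(),
            "namespace": t.namespace,
            "multiplicity": final.multiplicity[t],
        }
        for t in sorted(final.features)
    ]
    return pd.DataFrame(rows, columns=["term", "namespace", "multiplicity"])
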