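"""Hypergeometric enrichment encoding of genes by their network neighborhoods.

Each gene ``g`` is represented by one enrichment score per annotation term.
The evaluated gene set ``G`` is the closed neighborhood of ``g`` in the
interaction network (``g`` plus its direct partners; an ``--open-neighborhood``
style switch gives the partners-only reading). For a term annotating ``M`` of
the ``N`` background genes, with ``n = |G|`` and ``m`` annotated members of
``G``, the score is

    ES(g, term) = -log10 P(X >= m),   X ~ Hypergeometric(N, M, n)

i.e. the upper-tail probability that a random size-``n`` draw contains at
least ``m`` annotated genes. ``m = 0`` gives probability 1 and score 0;
underflowing tails are capped at :data:`SCORE_CAP` so matrices stay finite.
"""

from __future__ import annotations

from typing import List, Sequence, Set

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .types import AnnotationCorpus, FeatureMatrix, InteractionNetwork, TermId

#: -log10 score assigned when the tail probability underflows double precision.
SCORE_CAP = 300.0


def neighborhood(gene: str, net: InteractionNetwork, closed: bool = True) -> Set[str]:
    """Evaluated gene set for ``gene``: closed (default) or open neighborhood.

    A gene absent from the network has no partners; the closed convention
    still yields ``{gene}`` so its query is well defined (n = 1).
    """
    nbrs = net.neighbors(gene)
    return (nbrs | {gene}) if closed else nbrs


def hypergeom_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N, M, n).

    Equals the combinatorial sum over k = m..n of
    C(M, k) C(N-M, n-k) / C(N, n), with impossible terms contributing 0.
    """
    _validate_counts(N, M, n, m)
    if m == 0:
        return 1.0
    # sf(m-1) = P(X >= m); scipy's hypergeom is numerically stable here
    p = float(stats.hypergeom.sf(m - 1, N, M, n))
    return min(max(p, 0.0), 1.0)


def _validate_counts(N: int, M: int, n: int, m: int) -> None:
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= M <= N:
        raise ValueError(f"require 0 <= M <= N, got M={M}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"require 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= m <= min(n, M):
        raise ValueError(f"require 0 <= m <= min(n, M), got m={m}, n={n}, M={M}")


def enrichment_score(
    gene: str,
    term: TermId,
    net: InteractionNetwork,
    corpus: AnnotationCorpus,
    closed: bool = True,
) -> float:
    """Single-gene, single-term enrichment score (-log10 upper-tail p)."""
    if gene not in corpus.background:
        raise ValueError(f"gene {gene!r} is not in the annotation background")
    G = neighborhood(gene, net, closed=closed) & corpus.background
    annotated = corpus.term_to_genes[term]
    m = len(G & annotated)
    if m == 0:
        return 0.0
    p = hypergeom_upper_tail(corpus.N, len(annotated), len(G), m)
    if p < 1e-300:
        return SCORE_CAP
    return min(-np.log10(p), SCORE_CAP)


def encode_genes(
    genes: Sequence[str],
    net: InteractionNetwork,
    corpus: AnnotationCorpus,
    closed: bool = True,
) -> FeatureMatrix:
    """Encode genes into the full enrichment-score matrix.

    One row per input gene, one column per term in the corpus'
    ``term_order`` (all GO terms, then all KEGG pathways). Vectorized over
    terms per gene; deterministic and order-equivariant in the gene list.
    """
    encoder = NeighborhoodEnrichmentEncoder(net=net, corpus=corpus, closed=closed)
    encoder.fit(list(genes))
    values = encoder.transform(list(genes))
    return FeatureMatrix(
        genes=list(genes), features=list(corpus.term_order), values=values
    )


class NeighborhoodEnrichmentEncoder(TransformerMixin, BaseEstimator):
    """Transformer mapping gene ids to neighborhood enrichment-score vectors.

    Parameters
    ----------
    net : InteractionNetwork
        Source of direct neighbors.
    corpus : AnnotationCorpus
        Term annotations, background universe, and feature ordering.
    closed : bool, default=True
        Include the gene itself in the evaluated set (closed neighborhood).

    Attributes
    ----------
    feature_names_ : list of TermId
        Column order of the transformed output (corpus ``term_order``).
    n_features_out_ : int
        Number of enrichment-score features.
    """

    def __init__(
        self,
        net: InteractionNetwork,
        corpus: AnnotationCorpus,
        closed: bool = True,
    ) -> None:
        self.net = net
        self.corpus = corpus
        self.closed = closed

    def fit(self, X: Sequence[str], y=None) -> "NeighborhoodEnrichmentEncoder":
        """Precompute the background index and term-membership matrix."""
        bg = sorted(self.corpus.background)
        self._gene_index = {g: i for i, g in enumerate(bg)}
        n_bg, n_terms = len(bg), self.corpus.n_terms
        membership = np.zeros((n_bg, n_terms), dtype=bool)
        for j, term in enumerate(self.corpus.term_order):
            for g in self.corpus.term_to_genes[term]:
                membership[self._gene_index[g], j] = True
        self._membership = membership
        self._M = membership.sum(axis=0)
        self.feature_names_ = list(self.corpus.term_order)
        self.n_features_out_ = n_terms
        return self

    def transform(self, X: Sequence[str]) -> np.ndarray:
        """Return the (len(X), n_terms) matrix of enrichment scores."""
        if not hasattr(self, "_membership"):
            raise RuntimeError("encoder must be fitted before transform")
        genes = list(X)
        N = self.corpus.N
        out = np.zeros((len(genes), self.n_features_out_), dtype=float)
        for i, gene in enumerate(genes):
            if gene not in self._gene_index:
                raise ValueError(
                    f"gene {gene!r} is not in the annotation background"
                )
            G = neighborhood(gene, self.net, closed=self.closed)
            rows = [self._gene_index[g] for g in G if g in self._gene_index]
            n = len(rows)
            if n == 0:
                continue
            m = self._membership[rows].sum(axis=0)
            hit = m > 0
            if not np.any(hit):
                continue
            p = stats.hypergeom.sf(m[hit] - 1, N, self._M[hit], n)
            with np.errstate(divide="ignore"):
                scores = np.where(p < 1e-300, SCORE_CAP, -np.log10(np.maximum(p, 1e-300)))
            out[i, hit] = np.minimum(scores, SCORE_CAP)
        return out

    def encode(self, genes: Sequence[str]) -> FeatureMatrix:
        """Convenience wrapper returning a :class:`FeatureMatrix`."""
        return FeatureMatrix(
            genes=list(genes),
            features=list(self.feature_names_),
            values=self.transform(genes),
        )
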