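"""Shared domain types for the enrichment / feature-selection pipeline.

Gene identifiers are opaque strings (Ensembl-style tokens); terms carry a
namespace tag distinguishing Gene Ontology terms from KEGG pathways. The
annotation corpus fixes the feature coordinate system: GO terms first, then
KEGG pathways, each in first-appearance (file) order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import networkx as nx
import numpy as np

GO = "GO"
KEGG = "KEGG"
NAMESPACES = (GO, KEGG)


@dataclass(frozen=True, order=True)
class TermId:
    """A GO term or KEGG pathway identifier.

    Parameters
    ----------
    namespace : str
        Either ``"GO"`` or ``"KEGG"``.
    id : str
        The bare term token, e.g. ``"0008150"`` or ``"hsa04610"``.
    """

    namespace: str
    id: str

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid term id {self.id!r}")

    def token(self) -> str:
        """Serialized form ``namespace:id`` used in file headers."""
        return f"{self.namespace}:{self.id}"

    @classmethod
    def from_token(cls, token: str) -> "TermId":
        ns, _, ident = token.partition(":")
        return cls(ns, ident)


def validate_gene_id(gene: str) -> str:
    if not gene or any(c.isspace() for c in gene):
        raise ValueError(f"invalid gene id {gene!r}")
    return gene


class InteractionNetwork:
    """Undirected gene interaction graph with direct-neighbor lookup.

    Thin wrapper over a :class:`networkx.Graph`; self-loops are rejected and
    edges are unordered pairs, so neighbor lookup is symmetric by
    construction.
    """

    def __init__(self, graph: Optional[nx.Graph] = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValueError(f"network contains self-loops: {loops[:3]}")

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple], nodes: Iterable[str] = ()
    ) -> "InteractionNetwork":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                continue
            g.add_edge(a, b)
        return cls(g)

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> Set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def neighbors(self, gene: str) -> Set[str]:
        """Direct interaction partners of ``gene`` (empty set if absent)."""
        if gene not in self.graph:
            return set()
        return set(self.graph.neighbors(gene))

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0


@dataclass
class AnnotationCorpus:
    """Term -> annotated-gene-set maps for the GO and KEGG namespaces.

    ``background`` is the reference gene universe; ``N = |background|`` plays
    the role of the total number of proteins in the hypergeometric test.
    ``term_order`` is the fixed feature ordering (all GO, then all KEGG).
    """

    term_to_genes: Dict[TermId, frozenset]
    background: frozenset
    term_order: List[TermId]

    def __post_init__(self) -> None:
        if len(self.background) < 1:
            raise ValueError("background must contain at least one gene")
        for term, genes in self.term_to_genes.items():
            if not genes <= self.background:
                missing = sorted(genes - self.background)[:3]
                raise ValueError(
                    f"term {term.token()} annotates genes outside the "
                    f"background, e.g. {missing}"
                )
        if set(self.term_order) != set(self.term_to_genes):
            raise ValueError("term_order must enumerate exactly the corpus terms")

    @property
    def N(self) -> int:
        return len(self.background)

    def M(self, term: TermId) -> int:
        return len(self.term_to_genes[term])

    @property
    def n_terms(self) -> int:
        return len(self.term_order)

    def terms_in(self, namespace: str) -> List[TermId]:
        return [t for t in self.term_order if t.namespace == namespace]


@dataclass
class TermHierarchy:
    """Child -> parents map over GO terms, with namespace roots.

    Used only for category-level reporting: each root's children act as
    categories (biological process / cellular component / molecular function
    analogues) and membership is via descendant closure.
    """

    parent_of: Dict[TermId, Set[TermId]]
    roots: List[TermId]

    def children(self, term: TermId) -> Set[TermId]:
        return {c for c, parents in self.parent_of.items() if term in parents}

    def descendants(self, term: TermId) -> Set[TermId]:
        """All strict descendants of ``term`` (terminates: hierarchy is acyclic)."""
        out: Set[TermId] = set()
        frontier = self.children(term)
        while frontier:
            out |= frontier
            nxt: Set[TermId] = set()
            for t in frontier:
                nxt |= self.children(t)
            frontier = nxt - out
        return out

    def category_terms(self) -> List[TermId]:
        """Children of the namespace roots, in stable sorted order."""
        cats: List[TermId] = []
        for root in self.roots:
            cats.extend(sorted(self.children(root)))
        return cats


@dataclass
class LabeledGeneSet:
    """Ordered positive (disease) genes and negative-universe genes."""

    positives: List[str]
    negatives: List[str]

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"positives and negatives overlap: {sorted(overlap)[:3]}")


@dataclass
class FeatureMatrix:
    """Genes x terms matrix of enrichment scores with optional binary labels."""

    genes: List[str]
    features: List[TermId]
    values: np.ndarray
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.features)):
            raise ValueError(
                f"shape {self.values.shape} != ({len(self.genes)}, {len(self.features)})"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("enrichment scores must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.genes),):
                raise ValueError("labels length must match number of genes")

    @property
    def shape(self):
        return self.values.shape

    def subset_genes(self, genes: Sequence[str], labels=None) -> "FeatureMatrix":
        index = {g: i for i, g in enumerate(self.genes)}
        rows = [index[g] for g in genes]
        return FeatureMatrix(
            genes=list(genes),
            features=list(self.features),
            values=self.values[rows],
            labels=None if labels is None else np.asarray(labels, dtype=int),
        )

    def subset_features(self, features: Sequence[TermId]) -> "FeatureMatrix":
        index = {t: j for j, t in enumerate(self.features)}
        cols = [index[t] for t in features]
        return FeatureMatrix(
            genes=list(self.genes),
            features=list(features),
            values=self.values[:, cols],
            labels=self.labels,
        )


@dataclass
class RunConfig:
    """Run-wide configuration shared by the CLI and the pipeline."""

    seed: int = 0
    negative_ratio: int = 50
    n_splits: int = 10
    cramer_threshold: float = 0.1
    max_ranked_features: int = 500
    cv_folds: int = 10
    svm_kernel: str = "linear"
    svm_c: float = 1.0
    svm_degree: int = 1
    svm_gamma: str | float = "scale"
    discretization: str = "three_state_mean_sd"
    closed_neighborhood: bool = True
    min_edge_score: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("negative_ratio", "n_splits", "max_ranked_features", "cv_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.cramer_threshold <= 1.0:
            raise ValueError("cramer_threshold must lie in [0, 1]")


@dataclass
class RankedFeatureLists:
    """MaxRel (relevance-only) and mRMR (greedy MID) feature orderings."""

    maxrel: List[TermId]
    mrmr: List[TermId]
    relevance: Dict[TermId, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.maxrel)) != len(self.maxrel):
            raise ValueError("maxrel list contains duplicates")
        if len(set(self.mrmr)) != len(self.mrmr):
            raise ValueError("mrmr list contains duplicates")
        if self.maxrel and self.mrmr and self.maxrel[0] != self.mrmr[0]:
            raise ValueError("mrmr list must seed with the most relevant feature")
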