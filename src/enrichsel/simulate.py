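"""Synthetic networks, annotation corpora, and labeled gene sets.

Emulates the statistical structure the method assumes: a random
(Erdős–Rényi) interaction network, term annotations drawn independently at a
base rate, and a planted subset of "informative" terms whose annotation
probability is elevated for every gene within distance one of a positive
gene. Because the encoder scores closed neighborhoods, planting signal in
the neighborhoods of positives is exactly the structure the pipeline should
detect; ``signal_strength`` controls the effect size and
``base_annot_prob`` the background noise.

A toy three-category hierarchy (one category per namespace root, GO terms
assigned round-robin) mirrors the biological-process / cellular-component /
molecular-function split so category reporting is exercisable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Set, Tuple

import networkx as nx
import numpy as np

from . import io as esio
from .types import (
    GO,
    KEGG,
    AnnotationCorpus,
    InteractionNetwork,
    LabeledGeneSet,
    TermHierarchy,
    TermId,
)

ROOT_NAMES = ("BP", "CC", "MF")


@dataclass
class SyntheticSpec:
    """Generator settings; defaults are the package's reference conditions.

    200 genes with edge probability 0.03 give sparse closed neighborhoods of
    ~7 genes (degree ~6), a desk-scale stand-in for a thresholded
    protein-interaction network. 15 positives, 20 informative terms among
    300 GO + 40 KEGG, base annotation probability 0.05 and signal strength
    0.5 define the reference planted-signal condition; signal 0 is the null.
    """

    n_genes: int = 200
    n_go_terms: int = 300
    n_kegg_terms: int = 40
    edge_prob: float = 0.03
    n_positives: int = 15
    n_informative_terms: int = 20
    signal_strength: float = 0.5
    base_annot_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.edge_prob < 1.0:
            raise ValueError("edge_prob must lie in (0, 1)")
        if not 0.0 < self.base_annot_prob < 1.0:
            raise ValueError("base_annot_prob must lie in (0, 1)")
        if self.signal_strength < 0.0:
            raise ValueError("signal_strength must be >= 0")
        if self.n_positives >= self.n_genes:
            raise ValueError("n_positives must be smaller than n_genes")
        if self.n_informative_terms > self.n_go_terms + self.n_kegg_terms:
            raise ValueError("more informative terms than terms")


def _gene_names(n: int) -> List[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def _term_ids(spec: SyntheticSpec) -> List[TermId]:
    go = [TermId(GO, f"T{i:04d}") for i in range(1, spec.n_go_terms + 1)]
    kegg = [TermId(KEGG, f"P{i:04d}") for i in range(1, spec.n_kegg_terms + 1)]
    return go + kegg


def generate(
    spec: SyntheticSpec,
) -> Tuple[InteractionNetwork, AnnotationCorpus, TermHierarchy, LabeledGeneSet, Set[TermId]]:
    """Draw one synthetic instance; same seed gives bit-identical output.

    Returns the network, annotation corpus, toy hierarchy, labeled gene set
    (negatives = every non-positive gene), and the planted informative terms.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)

    graph = nx.fast_gnp_random_graph(
        spec.n_genes, spec.edge_prob, seed=int(rng.integers(2**31))
    )
    graph = nx.relabel_nodes(graph, dict(enumerate(genes)))
    net = InteractionNetwork(graph)

    pos_idx = rng.choice(spec.n_genes, size=spec.n_positives, replace=False)
    positives = [genes[i] for i in sorted(pos_idx)]
    negatives = [g for g in genes if g not in set(positives)]

    terms = _term_ids(spec)
    planted_idx = rng.choice(len(terms), size=spec.n_informative_terms, replace=False)
    planted = {terms[i] for i in sorted(planted_idx)}

    # genes within distance 1 of a positive carry elevated annotation odds
    carriers: Set[str] = set()
    for p in positives:
        carriers |= net.neighbors(p) | {p}
    p_signal = min(1.0, spec.base_annot_prob + spec.signal_strength)
    gene_index = {g: i for i, g in enumerate(genes)}
    carrier_rows = [gene_index[g] for g in carriers]

    term_to_genes = {}
    for term in terms:
        probs = np.full(spec.n_genes, spec.base_annot_prob)
        if term in planted:
            probs[carrier_rows] = p_signal
        draws = rng.random(spec.n_genes) < probs
        term_to_genes[term] = frozenset(g for g, d in zip(genes, draws) if d)

    corpus = AnnotationCorpus(
        term_to_genes=term_to_genes,
        background=frozenset(genes),
        term_order=terms,
    )
    hierarchy = _toy_hierarchy(spec)
    labeled = LabeledGeneSet(positives=positives, negatives=negatives)
    return net, corpus, hierarchy, labeled, planted


def _toy_hierarchy(spec: SyntheticSpec) -> TermHierarchy:
    """Three roots, one category child each; GO terms dealt round-robin."""
    roots = [TermId(GO, f"root_{name}") for name in ROOT_NAMES]
    categories = [TermId(GO, f"cat_{name}") for name in ROOT_NAMES]
    parent_of = {cat: {root} for cat, root in zip(categories, roots)}
    for i in range(1, spec.n_go_terms + 1):
        term = TermId(GO, f"T{i:04d}")
        parent_of[term] = {categories[(i - 1) % len(categories)]}
    return TermHierarchy(parent_of=parent_of, roots=roots)


#: filenames written by :func:`emit`
EMITTED_FILES = (
    "network.tsv",
    "annotations_go.tsv",
    "annotations_kegg.tsv",
    "hierarchy.tsv",
    "positives.txt",
)


def emit(spec: SyntheticSpec, out_dir) -> dict:
    """Write one synthetic instance to ``out_dir`` in the pipeline formats.

    Writes exactly the five files in :data:`EMITTED_FILES`; negatives are
    recoverable as the annotation background minus the positive list, and the
    planted terms are returned (ground truth, not a pipeline input).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    net, corpus, hierarchy, labeled, planted = generate(spec)
    esio.write_network(net, out_dir / "network.tsv")
    esio.write_annotations(
        corpus, out_dir / "annotations_go.tsv", out_dir / "annotations_kegg.tsv"
    )
    esio.write_hierarchy(hierarchy, out_dir / "hierarchy.tsv")
    esio.write_gene_list(labeled.positives, out_dir / "positives.txt")
    return {
        "files": [str(out_dir / name) for name in EMITTED_FILES],
        "n_genes": spec.n_genes,
        "n_edges": net.n_edges,
        "N": corpus.N,
        "planted_terms": sorted(t.token() for t in planted),
    }
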