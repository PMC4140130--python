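"""Readers and writers for the pipeline's plain-text formats.

Formats (all tab-separated, '#' starts a comment line):

* network:      ``geneA<TAB>geneB[<TAB>score]``
* annotations:  ``gene<TAB>term`` (one file per namespace)
* hierarchy:    ``child<TAB>parent`` over term tokens
* gene list:    one gene id per line
* feature matrix: header ``gene<TAB>term...[<TAB>label]``, one row per gene
* run config:   YAML mapping of :class:`~enrichsel.types.RunConfig` fields
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
import yaml

from .types import (
    GO,
    KEGG,
    AnnotationCorpus,
    FeatureMatrix,
    InteractionNetwork,
    RunConfig,
    TermHierarchy,
    TermId,
    validate_gene_id,
)

logger = logging.getLogger("enrichsel")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _rows(path) -> Iterable[tuple[int, List[str]]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split()


def read_network(path, min_score: Optional[float] = None) -> InteractionNetwork:
    """Read a two- or three-column edge list into an undirected network.

    Duplicate rows and reversed duplicates collapse into a single edge;
    self-loop rows are dropped with a warning. When ``min_score`` is given,
    rows whose third column falls below it are skipped.
    """
    import networkx as nx

    g = nx.Graph()
    n_loops = 0
    for lineno, fields in _rows(path):
        if len(fields) not in (2, 3):
            raise ParseError(
                f"{path}:{lineno}: expected 2-3 columns, got {len(fields)}"
            )
        a, b = validate_gene_id(fields[0]), validate_gene_id(fields[1])
        if min_score is not None and len(fields) == 3:
            try:
                score = float(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad score {fields[2]!r}") from exc
            if score < min_score:
                continue
        if a == b:
            n_loops += 1
            continue
        g.add_edge(a, b)
    if n_loops:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_loops)
    return InteractionNetwork(g)


def write_network(net: InteractionNetwork, path) -> None:
    # edge-list format cannot carry isolated nodes; callers persist those via gene lists
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            fh.write(f"{a}\t{b}\n")


def _read_annotation_file(path, namespace: str):
    """Return (ordered terms, term -> gene set) for one gene<TAB>term file."""
    order: List[TermId] = []
    mapping: dict[TermId, set] = {}
    n_rows = 0
    for lineno, fields in _rows(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        gene = validate_gene_id(fields[0])
        term = TermId(namespace, fields[1])
        if term not in mapping:
            mapping[term] = set()
            order.append(term)
        mapping[term].add(gene)
        n_rows += 1
    if n_rows == 0:
        raise ParseError(f"{path}: empty annotation file (no features would exist)")
    return order, mapping


def read_annotations(
    path_go,
    path_kegg,
    background_path=None,
    extra_background: Iterable[str] = (),
) -> AnnotationCorpus:
    """Read GO and KEGG annotation tables into a corpus.

    The background defaults to the union of every gene seen in either
    annotation file plus ``extra_background`` (typically the network's node
    set, merged by the caller); an explicit background file overrides this.
    """
    go_order, go_map = _read_annotation_file(path_go, GO)
    kegg_order, kegg_map = _read_annotation_file(path_kegg, KEGG)
    term_to_genes = {t: frozenset(gs) for t, gs in {**go_map, **kegg_map}.items()}
    if background_path is not None:
        background = frozenset(read_gene_list(background_path))
    else:
        background = frozenset(
            set().union(*term_to_genes.values(), set(extra_background))
        )
    return AnnotationCorpus(
        term_to_genes=term_to_genes,
        background=background,
        term_order=go_order + kegg_order,
    )


def write_annotations(corpus: AnnotationCorpus, path_go, path_kegg) -> None:
    with open(path_go, "w") as fgo, open(path_kegg, "w") as fkegg:
        for term in corpus.term_order:
            fh = fgo if term.namespace == GO else fkegg
            for gene in sorted(corpus.term_to_genes[term]):
                fh.write(f"{gene}\t{term.id}\n")


def read_hierarchy(path) -> TermHierarchy:
    """Read a child<TAB>parent table of GO term tokens.

    Roots are terms appearing only as parents. Cycles are rejected.
    """
    import networkx as nx

    parent_of: dict[TermId, Set[TermId]] = {}
    dag = nx.DiGraph()
    for lineno, fields in _rows(path):
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
        child, parent = TermId(GO, fields[0]), TermId(GO, fields[1])
        parent_of.setdefault(child, set()).add(parent)
        dag.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(dag):
        raise ParseError(f"{path}: hierarchy contains a cycle")
    children = set(parent_of)
    parents = set().union(*parent_of.values()) if parent_of else set()
    roots = sorted(parents - children)
    return TermHierarchy(parent_of=parent_of, roots=roots)


def write_hierarchy(h: TermHierarchy, path) -> None:
    with open(path, "w") as fh:
        for child in sorted(h.parent_of):
            for parent in sorted(h.parent_of[child]):
                fh.write(f"{child.id}\t{parent.id}\n")


def read_gene_list(path) -> List[str]:
    """One gene id per line; duplicates dropped (first kept) with a warning."""
    seen: Set[str] = set()
    out: List[str] = []
    n_dup = 0
    for _lineno, fields in _rows(path):
        gene = validate_gene_id(fields[0])
        if gene in seen:
            n_dup += 1
            continue
        seen.add(gene)
        out.append(gene)
    if n_dup:
        logger.warning("%s: dropped %d duplicate gene id(s)", path, n_dup)
    if not out:
        raise ParseError(f"{path}: no gene ids found")
    return out


def write_gene_list(genes: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_feature_matrix(m: FeatureMatrix, path) -> None:
    """Write a feature matrix as TSV, lossless to 12 significant digits."""
    df = pd.DataFrame(m.values, index=m.genes, columns=[t.token() for t in m.features])
    df.index.name = "gene"
    if m.labels is not None:
        df["label"] = m.labels
    df.to_csv(path, sep="\t", float_format="%.12g")


def read_feature_matrix(path) -> FeatureMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    features = [TermId.from_token(c) for c in df.columns]
    return FeatureMatrix(
        genes=[str(g) for g in df.index],
        features=features,
        values=df.to_numpy(dtype=float),
        labels=labels,
    )


def read_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {k: v for k, v in data.items() if k in RunConfig.__dataclass_fields__}
    return RunConfig(**known)


def write_run_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(vars(config), fh, sort_keys=True)
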