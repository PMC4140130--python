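import numpy as np
import pytest

from enrichsel import SyntheticSpec, generate
from enrichsel.types import GO, KEGG, AnnotationCorpus, InteractionNetwork, TermId


@pytest.fixture(scope="session")
def default_instance():
    """One default synthetic instance shared by read-only tests."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def tiny_spec():
    """Small spec for fast end-to-end pipeline tests."""
    return SyntheticSpec(
        n_genes=80,
        n_go_terms=40,
        n_kegg_terms=10,
        edge_prob=0.06,
        n_positives=10,
        n_informative_terms=8,
        signal_strength=0.6,
        base_annot_prob=0.05,
        seed=7,
    )


@pytest.fixture()
def toy_corpus():
    """Hand-built 20-gene corpus matching the worked hypergeometric example.

    Gene g01 sits at the center of a 5-star (closed neighborhood of size 6);
    term T1 annotates 5 background genes, 3 of which fall in that
    neighborhood, so the query is (N=20, M=5, n=6, m=3).
    """
    genes = [f"g{i:02d}" for i in range(1, 21)]
    net = InteractionNetwork.from_edges(
        [("g01", g) for g in ["g02", "g03", "g04", "g05", "g06"]], nodes=genes
    )
    t1 = TermId(GO, "T1")
    p1 = TermId(KEGG, "P1")
    corpus = AnnotationCorpus(
        term_to_genes={
            t1: frozenset({"g02", "g03", "g04", "g10", "g11"}),
            p1: frozenset({"g15"}),
        },
        background=frozenset(genes),
        term_order=[t1, p1],
    )
    return net, corpus, t1, p1
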