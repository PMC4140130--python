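import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enrichsel import (
    SCORE_CAP,
    SyntheticSpec,
    encode_genes,
    enrichment_score,
    generate,
    hypergeom_upper_tail,
    neighborhood,
)
from enrichsel.enrichment import NeighborhoodEnrichmentEncoder
from enrichsel.types import GO, AnnotationCorpus, InteractionNetwork, TermId

from .oracles import hypergeom_tail_exact


class TestNeighborhood:
    def test_star_graph_closed(self):
        net = InteractionNetwork.from_edges(
            [("c", f"l{i}") for i in range(1, 5)]
        )
        assert neighborhood("c", net) == {"c", "l1", "l2", "l3", "l4"}
        assert neighborhood("l1", net) == {"l1", "c"}

    def test_isolated_gene_closed_is_singleton(self):
        net = InteractionNetwork.from_edges([], nodes=["g"])
        assert neighborhood("g", net) == {"g"}
        assert neighborhood("absent", net) == {"absent"}

    def test_open_neighborhood_excludes_gene(self):
        net = InteractionNetwork.from_edges([("a", "b")])
        assert neighborhood("a", net, closed=False) == {"b"}

    def test_size_is_degree_plus_one(self, default_instance):
        net = default_instance[0]
        for g in sorted(net.nodes)[:50]:
            assert len(neighborhood(g, net)) == net.degree(g) + 1


class TestHypergeomUpperTail:
    def test_m_zero_is_one(self):
        assert hypergeom_upper_tail(10, 3, 4, 0) == 1.0

    def test_fully_annotated_background(self):
        assert hypergeom_upper_tail(10, 10, 6, 6) == 1.0

    def test_worked_example_matches_exact_enumeration(self):
        expected = float(hypergeom_tail_exact(20, 5, 6, 3))
        got = hypergeom_upper_tail(20, 5, 6, 3)
        assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("N", [5, 9, 13])
    def test_small_lattice_matches_exact_enumeration(self, N):
        for M in range(N + 1):
            for n in range(N + 1):
                for m in range(min(n, M) + 1):
                    exact = float(hypergeom_tail_exact(N, M, n, m))
                    assert hypergeom_upper_tail(N, M, n, m) == pytest.approx(
                        exact, rel=1e-12
                    )

    @given(
        N=st.integers(2, 40),
        M=st.integers(0, 40),
        n=st.integers(1, 40),
        m=st.integers(0, 40),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_nondecreasing_in_m(self, N, M, n, m):
        M, n = min(M, N), min(n, N)
        m = min(m, min(n, M))
        if m == 0:
            return
        assert hypergeom_upper_tail(N, M, n, m) <= hypergeom_upper_tail(
            N, M, n, m - 1
        ) + 1e-15

    @pytest.mark.parametrize("args", [(0, 0, 0, 0), (10, 11, 3, 1), (10, 3, 11, 1), (10, 3, 4, 4)])
    def test_invalid_counts_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(*args)


class TestEnrichmentScore:
    def test_no_annotated_neighbor_scores_zero(self, toy_corpus):
        net, corpus, _, p1 = toy_corpus
        assert enrichment_score("g01", p1, net, corpus) == 0.0

    def test_worked_example_score(self, toy_corpus):
        net, corpus, t1, _ = toy_corpus
        expected = -np.log10(float(hypergeom_tail_exact(20, 5, 6, 3)))
        assert enrichment_score("g01", t1, net, corpus) == pytest.approx(
            expected, rel=1e-12
        )

    def test_gene_outside_background_errors(self, toy_corpus):
        net, corpus, t1, _ = toy_corpus
        with pytest.raises(ValueError, match="background"):
            enrichment_score("nope", t1, net, corpus)


class TestEncodeAll:
    def test_matches_single_gene_scores(self, toy_corpus):
        net, corpus, t1, p1 = toy_corpus
        fm = encode_genes(["g01", "g10", "g15"], net, corpus)
        for i, g in enumerate(fm.genes):
            for j, t in enumerate(fm.features):
                assert fm.values[i, j] == pytest.approx(
                    enrichment_score(g, t, net, corpus), rel=1e-12
                )

    def test_zero_genes_keeps_term_dimension(self, toy_corpus):
        net, corpus, _, _ = toy_corpus
        fm = encode_genes([], net, corpus)
        assert fm.shape == (0, 2)

    def test_row_permutation_equivariance(self, toy_corpus):
        net, corpus, _, _ = toy_corpus
        genes = ["g01", "g02", "g10"]
        fm = encode_genes(genes, net, corpus)
        fm_rev = encode_genes(genes[::-1], net, corpus)
        np.testing.assert_array_equal(fm.values, fm_rev.values[::-1])

    def test_scores_finite_nonnegative(self, default_instance):
        net, corpus, _, labeled, _ = default_instance
        fm = encode_genes(labeled.positives, net, corpus)
        assert np.all(np.isfinite(fm.values))
        assert np.all(fm.values >= 0)
        assert np.all(fm.values <= SCORE_CAP)

    def test_open_vs_closed_differ_on_annotated_gene(self, toy_corpus):
        net, corpus, t1, _ = toy_corpus
        closed = enrichment_score("g02", t1, net, corpus, closed=True)
        open_ = enrichment_score("g02", t1, net, corpus, closed=False)
        assert closed != open_

    def test_encoder_transformer_api(self, toy_corpus):
        net, corpus, _, _ = toy_corpus
        enc = NeighborhoodEnrichmentEncoder(net=net, corpus=corpus).fit(["g01"])
        assert enc.n_features_out_ == 2
        X = enc.transform(["g01", "g02"])
        assert X.shape == (2, 2)
        params = enc.get_params()
        assert params["closed"] is True
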