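import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enrichsel import (
    CramerFilter,
    SyntheticSpec,
    cramers_v,
    discretize_feature,
    encode_genes,
    filter_features,
    generate,
)
from enrichsel.cramer import ZERO_VS_POSITIVE, discretize_matrix
from enrichsel.types import FeatureMatrix

from .oracles import cramers_v_2x2


class TestDiscretize:
    def test_constant_vector_single_bin(self):
        bins = discretize_feature(np.full(10, 3.5))
        assert len(np.unique(bins)) == 1

    def test_zero_vs_positive(self):
        np.testing.assert_array_equal(
            discretize_feature(np.array([0.0, 0.0, 0.0, 10.0]), ZERO_VS_POSITIVE),
            [0, 0, 0, 1],
        )

    def test_three_state_normal_proportions(self):
        rng = np.random.default_rng(0)
        bins = discretize_feature(rng.standard_normal(10_000))
        props = np.bincount(bins, minlength=3) / 10_000
        # normal CDF: P(X <= -1), P(-1 < X < 1), P(X >= 1)
        lo = stats.norm.cdf(-1)
        np.testing.assert_allclose(props, [lo, 1 - 2 * lo, lo], atol=0.02)

    def test_boundary_values_follow_interval_contract(self):
        # construct values with mu = 0, sigma = 1 exactly containing +/- 1
        v = np.array([-1.0, 1.0, -1.0, 1.0])
        assert discretize_feature(v).tolist() == [0, 2, 0, 2]

    def test_matrix_matches_per_column(self):
        rng = np.random.default_rng(1)
        X = rng.random((50, 6))
        X[:, 2] = 7.0
        cols = [discretize_feature(X[:, j]) for j in range(6)]
        np.testing.assert_array_equal(discretize_matrix(X), np.column_stack(cols))

    def test_empty_vector_errors(self):
        with pytest.raises(ValueError):
            discretize_feature(np.array([]))


class TestCramersV:
    def test_independent_table_is_zero(self):
        assert cramers_v(np.array([[10, 10], [10, 10]])) == 0.0

    def test_perfect_association_is_one(self):
        assert cramers_v(np.array([[20, 0], [0, 20]])) == pytest.approx(1.0)

    def test_2x2_closed_form(self):
        table = np.array([[30, 10], [10, 30]])
        assert cramers_v(table) == pytest.approx(cramers_v_2x2(30, 10, 10, 30))

    def test_degenerate_tables_score_zero(self):
        assert cramers_v(np.array([[5, 0], [7, 0]])) == 0.0
        assert cramers_v(np.array([[5, 3]])) == 0.0

    @given(
        st.lists(
            st.lists(st.integers(0, 30), min_size=2, max_size=2),
            min_size=2,
            max_size=4,
        )
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_and_permutation_invariance(self, rows):
        table = np.array(rows)
        if table.sum() == 0:
            return
        v = cramers_v(table)
        assert 0.0 <= v <= 1.0
        assert cramers_v(table[::-1]) == pytest.approx(v)
        assert cramers_v(table[:, ::-1]) == pytest.approx(v)


def _labeled_matrix(seed, signal, n_neg=18):
    spec = SyntheticSpec(seed=seed, signal_strength=signal)
    net, corpus, _, labeled, planted = generate(spec)
    genes = labeled.positives + labeled.negatives[:n_neg]
    fm = encode_genes(genes, net, corpus)
    fm.labels = np.array([1] * len(labeled.positives) + [0] * n_neg)
    return fm, planted


class TestFilterFeatures:
    def test_threshold_zero_keeps_all(self):
        fm, _ = _labeled_matrix(seed=2, signal=0.5)
        survivors, values = filter_features(fm, threshold=0.0)
        assert survivors == fm.features
        assert set(values) == set(fm.features)

    def test_impossible_threshold_empties(self):
        fm, _ = _labeled_matrix(seed=2, signal=0.5)
        survivors, _ = filter_features(fm, threshold=1.01)
        assert survivors == []

    def test_survivors_preserve_term_order(self):
        fm, _ = _labeled_matrix(seed=2, signal=0.5)
        survivors, _ = filter_features(fm, threshold=0.3)
        order = {t: j for j, t in enumerate(fm.features)}
        assert [order[t] for t in survivors] == sorted(order[t] for t in survivors)

    def test_exact_threshold_value_is_kept(self):
        # feature with V == threshold must survive (strict-less exclusion)
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        y = np.array([0, 0, 1, 1])
        f = CramerFilter(threshold=1.0, scheme=ZERO_VS_POSITIVE).fit(X, y)
        assert f.scores_[0] == pytest.approx(1.0)
        assert f.get_support().tolist() == [True]

    def test_planted_terms_beat_median_null_v(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            fm, planted = _labeled_matrix(seed=200 + seed, signal=0.5)
            _, values = filter_features(fm, threshold=0.0)
            planted_v = [values[t] for t in fm.features if t in planted]
            other_v = [values[t] for t in fm.features if t not in planted]
            median_other = np.median(other_v)
            wins += np.mean([v > median_other for v in planted_v]) > 0.5
        assert wins > n_seeds / 2

    def test_null_run_filters_some_features_at_large_n(self):
        for seed in range(10):
            fm, _ = _labeled_matrix(seed=300 + seed, signal=0.0, n_neg=100)
            survivors, _ = filter_features(fm, threshold=0.1)
            assert len(survivors) < len(fm.features)

    def test_sklearn_selector_contract(self):
        fm, _ = _labeled_matrix(seed=2, signal=0.5)
        sel = CramerFilter(threshold=0.2).fit(fm.values, fm.labels)
        reduced = sel.transform(fm.values)
        assert reduced.shape == (fm.shape[0], sel.get_support().sum())
        assert sel.get_params()["threshold"] == 0.2
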