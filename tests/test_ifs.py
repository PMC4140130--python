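import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enrichsel import (
    ConfusionCounts,
    IncrementalFeatureSelector,
    RunConfig,
    cross_validate,
    metrics_from_confusion,
    run_ifs,
)
from enrichsel.ifs import _fold_indices, optimal_prefix, train_classifier
from enrichsel.types import GO, FeatureMatrix, RankedFeatureLists, TermId

from .oracles import metrics_direct


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics_from_confusion(ConfusionCounts(tp=39, tn=195, fp=0, fn=0))
        assert (m.acc, m.sp, m.sn, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_total_error(self):
        m = metrics_from_confusion(ConfusionCounts(tp=0, tn=0, fp=7, fn=5))
        assert m.acc == 0.0
        assert m.mcc == -1.0

    def test_direct_formula_oracle(self):
        c = ConfusionCounts(tp=30, fn=9, tn=160, fp=35)
        m = metrics_from_confusion(c)
        acc, sp, sn, mcc = metrics_direct(30, 160, 35, 9)
        assert (m.acc, m.sp, m.sn, m.mcc) == pytest.approx((acc, sp, sn, mcc))

    def test_zero_denominator_convention(self):
        m = metrics_from_confusion(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert m.sn == 0.0 and m.mcc == 0.0

    @given(
        tp=st.integers(0, 300),
        tn=st.integers(0, 300),
        fp=st.integers(0, 300),
        fn=st.integers(0, 300),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_identities(self, tp, tn, fp, fn):
        m = metrics_from_confusion(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        assert -1.0 <= m.mcc <= 1.0
        swapped = metrics_from_confusion(ConfusionCounts(tp=tn, tn=tp, fp=fn, fn=fp))
        assert abs(swapped.mcc) == pytest.approx(abs(m.mcc))
        P, N = tp + fn, tn + fp
        if P and N:
            assert m.acc == pytest.approx((m.sn * P + m.sp * N) / (P + N))


def _separable(n_pos=20, n_neg=30, n_extra=3, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([1] * n_pos + [0] * n_neg)
    signal = np.where(y == 1, 10.0, 0.0) + rng.normal(0, 0.1, size=y.size)
    X = np.column_stack([signal] + [rng.normal(size=y.size) for _ in range(n_extra)])
    return X, y


class TestCrossValidate:
    def test_separable_toy_all_correct(self):
        X, y = _separable()
        c = cross_validate(X[:, :1], y, folds=10, seed=1)
        assert (c.fp, c.fn) == (0, 0)
        assert (c.tp, c.tn) == (20, 30)

    def test_each_sample_tested_once_fold_sizes(self):
        y = np.array([1] * 39 + [0] * 195)
        folds = _fold_indices(y, 10, seed=0)
        test_sizes = sorted(len(te) for _, te in folds)
        assert set(test_sizes) <= {23, 24}
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test) == list(range(234))

    def test_permuted_labels_near_zero_mcc(self):
        rng = np.random.default_rng(0)
        X, y = _separable(n_pos=39, n_neg=195, n_extra=4)
        for seed in range(20):
            y_perm = rng.permutation(y)
            c = cross_validate(X[:, 1:], y_perm, folds=10, seed=seed)
            assert -0.25 <= metrics_from_confusion(c).mcc <= 0.25

    def test_missing_class_errors(self):
        X = np.zeros((20, 2))
        with pytest.raises(ValueError):
            cross_validate(X, np.ones(20, dtype=int), folds=10, seed=0)

    def test_deterministic_under_seed(self):
        X, y = _separable(seed=3)
        a = cross_validate(X, y, folds=5, seed=9)
        b = cross_validate(X, y, folds=5, seed=9)
        assert a == b


class TestTrainClassifier:
    def test_separable_training_accuracy(self):
        X, y = _separable()
        clf, predict = train_classifier(X[:, :1], y)
        assert np.array_equal(predict(X[:, :1]), y)

    def test_duplication_invariance_on_probe_grid(self):
        X, y = _separable(n_extra=1)
        _, predict_once = train_classifier(X, y)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        _, predict_twice = train_classifier(X2, y2)
        probe = np.column_stack(
            [np.linspace(-2, 12, 50), np.linspace(-3, 3, 50)]
        )
        assert np.array_equal(predict_once(probe), predict_twice(probe))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((5, 2)), np.ones(5, dtype=int))


class TestOptimalPrefix:
    def test_first_maximum_wins(self):
        assert optimal_prefix([0.2, 0.5, 0.5, 0.4]) == 2

    def test_single_point_curve(self):
        assert optimal_prefix([0.1]) == 1

    def test_empty_curve_errors(self):
        with pytest.raises(ValueError):
            optimal_prefix([])


class TestRunIFS:
    def _matrix(self, X, y):
        features = [TermId(GO, f"T{j}") for j in range(X.shape[1])]
        return FeatureMatrix(
            genes=[f"g{i}" for i in range(X.shape[0])],
            features=features,
            values=np.abs(X),
            labels=y,
        )

    def test_optimal_prefix_on_separable_data(self):
        X, y = _separable()
        fm = self._matrix(X, y)
        ranked = RankedFeatureLists(maxrel=fm.features, mrmr=fm.features)
        result = run_ifs(fm, ranked, config=RunConfig(cv_folds=5), seed=2)
        assert result.max_mcc == 1.0
        assert result.optimal_size == 1
        assert result.optimal_features == fm.features[:1]
        assert len(result.curve) == len(fm.features)

    def test_curve_reproducible_under_seed(self):
        X, y = _separable(seed=4)
        fm = self._matrix(X, y)
        ranked = RankedFeatureLists(maxrel=fm.features, mrmr=fm.features)
        r1 = run_ifs(fm, ranked, config=RunConfig(cv_folds=5), seed=8)
        r2 = run_ifs(fm, ranked, config=RunConfig(cv_folds=5), seed=8)
        assert r1.mccs == r2.mccs

    def test_selector_estimator_api(self):
        X, y = _separable()
        sel = IncrementalFeatureSelector(cv=5, random_state=1).fit(np.abs(X), y)
        assert sel.support_.sum() == sel.optimal_size_
        assert sel.transform(np.abs(X)).shape == (y.size, sel.optimal_size_)
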