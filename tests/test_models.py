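"""Lasso path, penalty selection rules, comparators and performance metrics."""

import numpy as np
import pytest

from motifgrammar import (
    ConfusionCounts,
    LassoPath,
    confusion,
    fdr,
    fit_comparators,
    fit_lasso_path,
    model_at,
    ppv,
    predict,
    roc_auc,
    select_lambda_1se,
    select_lambda_knowledge,
    sensitivity,
    specificity,
)
from motifgrammar.models import AnchorNotInformativeError, FittedModel


def toy_path(lambdas, coefs, means=None, ses=None, ids=None):
    lambdas = np.asarray(lambdas, dtype=float)
    coefs = np.asarray(coefs, dtype=float)
    n = len(lambdas)
    return LassoPath(
        lambdas=lambdas,
        coefficients=coefs,
        intercepts=np.zeros(n),
        cv_auc_mean=np.asarray(means if means is not None else np.zeros(n), dtype=float),
        cv_auc_se=np.asarray(ses if ses is not None else np.zeros(n), dtype=float),
        n_folds=10,
        seed=0,
        motif_ids=ids or [f"m{j}" for j in range(coefs.shape[1])],
    )


def noisy_data(rng, n=120, p=20, signal_col=None):
    X = rng.normal(size=(n, p))
    y = rng.integers(0, 2, size=n)
    if signal_col is not None:
        X[:, signal_col] = y * 2.0 + rng.normal(scale=0.1, size=n)
    return X, y


class TestLassoPath:
    def test_grid_and_zero_at_top(self, rng):
        X, y = noisy_data(rng, signal_col=0)
        path = fit_lasso_path(X, y, n_folds=5, seed=1)
        assert np.all(np.diff(path.lambdas) < 0)
        assert np.all(path.coefficients[0] == 0.0)
        assert len(path.lambdas) == 100
        assert path.lambdas[0] / path.lambdas[-1] == pytest.approx(1000.0)

    def test_seed_determinism(self, rng):
        X, y = noisy_data(rng, signal_col=2)
        a = fit_lasso_path(X, y, n_folds=5, seed=5)
        b = fit_lasso_path(X, y, n_folds=5, seed=5)
        np.testing.assert_array_equal(a.cv_auc_mean, b.cv_auc_mean)
        np.testing.assert_array_equal(a.coefficients, b.coefficients)

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        with pytest.raises(ValueError, match="class"):
            fit_lasso_path(X, np.ones(20, dtype=int), n_folds=5)

    def test_constant_column_gets_zero_coefficient(self, rng):
        X, y = noisy_data(rng, n=100, p=5, signal_col=1)
        X[:, 3] = 7.0
        path = fit_lasso_path(X, y, n_folds=5, seed=2)
        assert np.all(path.coefficients[:, 3] == 0.0)

    def test_perfect_separator_dominates_at_1se(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            X, y = noisy_data(rng, n=120, p=51, signal_col=7)
            path = fit_lasso_path(X, y, n_folds=10, seed=seed)
            model = model_at(path, select_lambda_1se(path))
            if model.active_features:
                top = max(model.active_features, key=lambda m: abs(model.active_features[m]))
                wins += top == "f7"
        assert wins >= 9

    def test_all_noise_cv_auc_near_half(self):
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            X, y = noisy_data(rng, n=100, p=20)
            path = fit_lasso_path(X, y, n_folds=5, seed=seed)
            aucs.append(path.cv_auc_mean)
        mean_curve = np.mean(aucs, axis=0)
        assert np.all(mean_curve >= 0.4) and np.all(mean_curve <= 0.6)


class TestSelection:
    def test_1se_spec_example(self):
        path = toy_path([1.0, 0.5, 0.1], np.zeros((3, 2)),
                        means=[0.60, 0.70, 0.72], ses=[0.05, 0.03, 0.02])
        assert select_lambda_1se(path) == 0.5

    def test_1se_all_equal_takes_largest(self):
        path = toy_path([1.0, 0.5, 0.1], np.zeros((3, 2)), means=[0.7, 0.7, 0.7])
        assert select_lambda_1se(path) == 1.0

    def test_1se_zero_se_unique_max(self):
        path = toy_path([1.0, 0.5, 0.1], np.zeros((3, 2)), means=[0.6, 0.65, 0.7])
        assert select_lambda_1se(path) == 0.1

    @pytest.mark.parametrize(
        "anchor_coefs,expect",
        [([0.0, 0.2, 0.3], 0.5), ([0.0, 0.0, 0.3], 0.1)],
    )
    def test_knowledge_rule(self, anchor_coefs, expect):
        coefs = np.column_stack([anchor_coefs, [0.1, 0.2, 0.3]])
        path = toy_path([1.0, 0.5, 0.1], coefs, ids=["anchor", "other"])
        assert select_lambda_knowledge(path, "anchor") == expect

    def test_knowledge_never_active_errors(self):
        path = toy_path([1.0, 0.5, 0.1], np.zeros((3, 2)), ids=["anchor", "other"])
        with pytest.raises(AnchorNotInformativeError):
            select_lambda_knowledge(path, "anchor")

    def test_knowledge_unknown_anchor(self):
        path = toy_path([1.0, 0.5], np.zeros((2, 1)), ids=["m0"])
        with pytest.raises(KeyError):
            select_lambda_knowledge(path, "nope")

    def test_knowledge_noncontiguous_warns(self):
        coefs = np.array([[0.0], [0.2], [0.0], [0.3]])
        path = toy_path([1.0, 0.5, 0.25, 0.1], coefs, ids=["anchor"])
        with pytest.warns(UserWarning, match="non-contiguous"):
            lam = select_lambda_knowledge(path, "anchor")
        assert lam == 0.5

    def test_knowledge_all_mode(self):
        coefs = np.array([[0.0, 0.1], [0.2, 0.1], [0.3, 0.1]])
        path = toy_path([1.0, 0.5, 0.1], coefs, ids=["a1", "a2"])
        assert select_lambda_knowledge(path, ["a1", "a2"], mode="any") == 1.0
        assert select_lambda_knowledge(path, ["a1", "a2"], mode="all") == 0.5


class TestPredict:
    def test_alignment_by_motif_id(self, rng):
        from motifgrammar.features import FeatureMatrix

        model = FittedModel(
            kind="lasso", motif_ids=["m0", "m1"], hyperparams={},
            active_features={"m1": 1.0}, coef=np.array([0.0, 1.0]), intercept=0.0,
        )
        X = rng.random((5, 2))
        fm = FeatureMatrix(["p%d" % i for i in range(5)], ["m0", "m1"], X)
        fm_swapped = FeatureMatrix(fm.peak_ids, ["m1", "m0"], X[:, [1, 0]])
        np.testing.assert_allclose(predict(model, fm), predict(model, fm_swapped))

    def test_missing_column_errors(self):
        from motifgrammar.features import FeatureMatrix

        model = FittedModel(
            kind="lasso", motif_ids=["m0", "m1"], hyperparams={},
            active_features={}, coef=np.zeros(2), intercept=0.0,
        )
        fm = FeatureMatrix(["p0"], ["m0"], np.array([[1.0]]))
        with pytest.raises(KeyError, match="m1"):
            predict(model, fm)

    def test_constant_model_constant_scores(self, rng):
        model = FittedModel(
            kind="lasso", motif_ids=["m0"], hyperparams={},
            active_features={}, coef=np.zeros(1), intercept=0.3,
        )
        scores = predict(model, rng.random((10, 1)))
        assert np.allclose(scores, scores[0])


class TestComparators:
    def test_separable_data_strong_auc(self, rng):
        X, y = noisy_data(rng, n=120, p=10, signal_col=0)
        tr, te = np.arange(0, 90), np.arange(90, 120)
        models = fit_comparators(X[tr], y[tr], n_folds=5, seed=0, n_trees=100)
        assert {m.kind for m in models} == {"linear_max_margin", "tree_ensemble"}
        for m in models:
            auc = roc_auc(predict(m, X[te]), y[te]).auc
            assert auc >= 0.9

    def test_permuted_labels_near_chance(self):
        aucs = {"linear_max_margin": [], "tree_ensemble": []}
        for seed in range(5):
            rng = np.random.default_rng(3000 + seed)
            X, y = noisy_data(rng, n=100, p=10, signal_col=0)
            yp = rng.permutation(y)
            tr, te = np.arange(0, 70), np.arange(70, 100)
            for m in fit_comparators(X[tr], yp[tr], n_folds=5, seed=seed, n_trees=100):
                aucs[m.kind].append(roc_auc(predict(m, X[te]), yp[te]).auc)
        for kind, vals in aucs.items():
            assert 0.3 <= np.mean(vals) <= 0.7, kind

    def test_seeded_c_reproducible(self, rng):
        X, y = noisy_data(rng, n=100, p=8, signal_col=1)
        a = fit_comparators(X, y, n_folds=5, seed=4, n_trees=50)[0]
        b = fit_comparators(X, y, n_folds=5, seed=4, n_trees=50)[0]
        assert a.hyperparams["C"] == b.hyperparams["C"]


class TestMetrics:
    def test_confusion_example(self):
        cm = confusion([0.9, 0.2], ["positive", "background"])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 0, 1, 0)

    def test_confusion_all_positive(self):
        cm = confusion([0.9, 0.8], ["positive", "background"], cutoff=0.5)
        assert cm.fn == 0 and cm.tn == 0 and cm.fp == 1

    def test_confusion_counting_oracle(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 40))
            scores = rng.random(n)
            labels = rng.integers(0, 2, size=n)
            cutoff = float(rng.random())
            cm = confusion(scores, labels, cutoff=cutoff)
            tp = sum(1 for s, y in zip(scores, labels) if s >= cutoff and y == 1)
            fp = sum(1 for s, y in zip(scores, labels) if s >= cutoff and y == 0)
            fn = sum(1 for s, y in zip(scores, labels) if s < cutoff and y == 1)
            tn = n - tp - fp - fn
            assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)

    def test_rate_examples(self):
        assert sensitivity(ConfusionCounts(3, 0, 0, 1)) == pytest.approx(0.75)
        cm = ConfusionCounts(tp=735, fp=265, tn=0, fn=0)
        assert ppv(cm) == pytest.approx(0.735)
        assert fdr(cm) == pytest.approx(0.265)

    def test_zero_denominator_sentinels(self):
        cm = ConfusionCounts(0, 0, 5, 5)
        assert np.isnan(ppv(cm)) and np.isnan(fdr(cm))
        assert np.isnan(sensitivity(ConfusionCounts(0, 3, 3, 0)))
        assert np.isnan(specificity(ConfusionCounts(3, 0, 0, 3)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestRoc:
    def test_perfect_and_tied(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]).auc == pytest.approx(1.0)
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]).auc == pytest.approx(0.5)

    def test_concordant_pair_example(self):
        roc = roc_auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_curve_shape(self, rng):
        roc = roc_auc(rng.random(50), rng.integers(0, 2, size=50))
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])
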