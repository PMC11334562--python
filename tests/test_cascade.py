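import numpy as np
import pytest
from sklearn.datasets import make_blobs
from sklearn.ensemble import RandomForestClassifier

from dpicdf.cascade import (
    CascadeClassifier,
    CascadeConfig,
    fit_cascade,
    fit_layer,
    layer_seeds,
    load_model,
    predict,
    predict_proba,
    save_model,
)

FAST = dict(trees_per_estimator=15, max_layers=3)


@pytest.fixture(scope="module")
def blobs():
    X, y = make_blobs(
        n_samples=120, centers=2, n_features=10, cluster_std=3.0, random_state=17
    )
    return X, y


class TestFitLayer:
    def test_oof_probability_shape_and_normalization(self, blobs):
        X, y = blobs
        cfg = CascadeConfig(**FAST, seed=1)
        estimators, oof = fit_layer(X, y, cfg, layer_index=0)
        assert len(estimators) == 4
        assert oof.shape == (120, 8)
        assert np.allclose(oof.reshape(120, 4, 2).sum(axis=2), 1.0)

    def test_deterministic_under_fixed_seed(self, blobs):
        X, y = blobs
        cfg = CascadeConfig(**FAST, seed=5)
        _, oof1 = fit_layer(X, y, cfg, layer_index=0)
        _, oof2 = fit_layer(X, y, cfg, layer_index=0)
        assert np.array_equal(oof1, oof2)

    def test_single_class_rejected(self, blobs):
        X, _ = blobs
        with pytest.raises(ValueError, match="both classes"):
            fit_layer(X, np.zeros(len(X), dtype=int), CascadeConfig(**FAST), 0)

    def test_single_internal_fold_rejected(self):
        with pytest.raises(ValueError, match="internal_cv_folds"):
            CascadeConfig(internal_cv_folds=1)


class TestFitCascade:
    def test_separable_data_reaches_high_validation_accuracy(self, blobs):
        X, y = blobs
        model = fit_cascade(X, y, CascadeConfig(**FAST, seed=2))
        assert model.layer_scores[model.best_layer] >= 0.95

    def test_max_layers_caps_growth(self, blobs):
        X, y = blobs
        cfg = CascadeConfig(trees_per_estimator=10, max_layers=1, seed=3)
        model = fit_cascade(X, y, cfg)
        assert model.n_layers == 1

    def test_layer2_input_dimension_is_d_plus_8(self, blobs):
        # the four-learner default augments with 4 x 2 probability columns
        X, y = blobs
        cfg = CascadeConfig(
            trees_per_estimator=10, max_layers=2, patience=2, seed=4
        )
        model = fit_cascade(X, y, cfg)
        if model.n_layers >= 2:
            expected = X.shape[1] + 8
            assert model.layers[1][1].n_features_in_ == expected
        # the arithmetic must hold regardless of how deep growth went
        estimators, oof = fit_layer(X, y, cfg, layer_index=0)
        X2 = np.hstack([X, oof])
        assert X2.shape[1] == X.shape[1] + 8

    def test_bit_identical_reruns(self, blobs):
        X, y = blobs
        cfg = CascadeConfig(**FAST, seed=6)
        p1 = predict_proba(fit_cascade(X, y, cfg), X)
        p2 = predict_proba(fit_cascade(X, y, cfg), X)
        assert np.array_equal(p1, p2)


class TestPredict:
    def test_probability_rows_sum_to_one(self, blobs):
        X, y = blobs
        model = fit_cascade(X, y, CascadeConfig(**FAST, seed=7))
        proba = predict_proba(model, X)
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_predict_is_argmax_with_negative_tie_rule(self, blobs):
        X, y = blobs
        model = fit_cascade(X, y, CascadeConfig(**FAST, seed=7))
        proba = predict_proba(model, X)
        labels = predict(model, X)
        assert set(labels.tolist()) <= {0, 1}
        assert np.array_equal(labels, (proba[:, 1] > proba[:, 0]).astype(int))

    def test_dimension_mismatch_rejected(self, blobs):
        X, y = blobs
        model = fit_cascade(X, y, CascadeConfig(**FAST, seed=7))
        with pytest.raises(ValueError, match="features"):
            predict_proba(model, X[:, :5])


class TestEquivalenceAndPersistence:
    def test_single_forest_single_layer_equals_plain_forest(self, blobs):
        # degenerate cascade = its own base learner, an exact oracle
        X, y = blobs
        cfg = CascadeConfig(
            estimators_per_layer=("rf",), trees_per_estimator=30,
            max_layers=1, seed=9,
        )
        model = fit_cascade(X, y, cfg)
        seed = int(layer_seeds(9, 0, 2)[0])
        reference = RandomForestClassifier(
            n_estimators=30, max_features="sqrt", random_state=seed, n_jobs=1
        ).fit(X, y)
        assert np.array_equal(predict(model, X), reference.predict(X))
        assert np.allclose(predict_proba(model, X), reference.predict_proba(X))

    def test_cascade_not_worse_than_single_forest_budget(self, blobs):
        # sanity: stacking never catastrophically underperforms one forest
        # with the same total tree budget (60 trees), over 5 seeds
        X, y = blobs
        rng = np.random.default_rng(0)
        test_idx = rng.choice(len(X), 40, replace=False)
        train_mask = np.ones(len(X), bool)
        train_mask[test_idx] = False
        Xtr, ytr, Xte, yte = X[train_mask], y[train_mask], X[test_idx], y[test_idx]
        for seed in range(5):
            cascade = fit_cascade(
                Xtr, ytr, CascadeConfig(trees_per_estimator=15, max_layers=2, seed=seed)
            )
            forest = RandomForestClassifier(
                n_estimators=60, max_features="sqrt", random_state=seed, n_jobs=1
            ).fit(Xtr, ytr)
            acc_cascade = (predict(cascade, Xte) == yte).mean()
            acc_forest = (forest.predict(Xte) == yte).mean()
            assert acc_cascade >= acc_forest - 0.02

    def test_serialization_round_trip_is_bit_identical(self, blobs, tmp_path):
        X, y = blobs
        model = fit_cascade(X, y, CascadeConfig(**FAST, seed=11))
        path = tmp_path / "model.joblib"
        save_model(model, path)
        loaded = load_model(path)
        assert np.array_equal(predict_proba(model, X), predict_proba(loaded, X))

    def test_classifier_wrapper_matches_functional_api(self, blobs):
        X, y = blobs
        cfg = CascadeConfig(**FAST, seed=12)
        clf = CascadeClassifier(cfg).fit(X, y)
        assert np.array_equal(clf.predict(X), predict(fit_cascade(X, y, cfg), X))
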