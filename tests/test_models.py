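import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tepmced.models import (
    FAMILIES,
    ModelConfig,
    build_model,
    calibrate_threshold,
    tune_and_fit,
)
from tepmced.nnet import MLPBinaryClassifier
from tepmced.resample import SMOTE, ResampleScalePipeline

from ._oracles import best_youden


def test_model_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(family="GBM")
    with pytest.raises(ValueError):
        ModelConfig(family="LR", cv_folds=1)
    with pytest.raises(ValueError):
        ModelConfig(family="LR", threshold_source="train")
    cfg = ModelConfig(family="RF")
    assert cfg.search_space and cfg.n_search_iters > 0


@given(st.data())
def test_threshold_calibration_attains_the_exhaustive_youden_maximum(data):
    n = data.draw(st.integers(min_value=6, max_value=40))
    scores = np.asarray(
        data.draw(
            st.lists(
                st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                min_size=n, max_size=n,
            )
        )
    )
    labels = np.asarray(data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)))
    if labels.min() == labels.max():
        return
    t = calibrate_threshold(scores, labels)
    j_best, _ = best_youden(scores, labels)
    pred = scores >= t
    j_t = pred[labels == 1].mean() + (~pred)[labels == 0].mean() - 1
    assert j_t == pytest.approx(j_best, abs=1e-9)


def test_threshold_separates_perfectly_separable_scores():
    scores = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
    labels = np.array([0, 0, 0, 1, 1, 1])
    t = calibrate_threshold(scores, labels)
    assert 0.3 < t <= 0.7
    assert ((scores >= t).astype(int) == labels).all()


def test_threshold_requires_both_classes():
    with pytest.raises(ValueError):
        calibrate_threshold(np.array([0.2, 0.8]), np.array([1, 1]))


def test_smote_balances_classes_with_points_on_minority_segments():
    rng = np.random.default_rng(0)
    Xmaj = rng.normal(0, 1, size=(40, 3))
    Xmin = rng.normal(4, 1, size=(10, 3))
    X = np.vstack([Xmaj, Xmin])
    y = np.array([0] * 40 + [1] * 10)
    Xr, yr = SMOTE(seed=1).fit_resample(X, y)
    assert (yr == 1).sum() == (yr == 0).sum() == 40
    # original rows are kept verbatim at the front
    np.testing.assert_array_equal(Xr[:50], X)
    # each synthetic row lies on a segment between two minority points
    for row in Xr[50:]:
        on_segment = False
        for a in range(10):
            for b in range(10):
                if a == b:
                    continue
                d = Xmin[b] - Xmin[a]
                t = (row - Xmin[a]) @ d / (d @ d)
                if -1e-9 <= t <= 1 + 1e-9 and np.allclose(Xmin[a] + t * d, row, atol=1e-9):
                    on_segment = True
                    break
            if on_segment:
                break
        assert on_segment


def test_smote_requires_two_classes_and_handles_singleton_minority():
    with pytest.raises(ValueError):
        SMOTE().fit_resample(np.zeros((3, 2)), np.array([1, 1, 1]))
    X = np.arange(10, dtype=float).reshape(5, 2)
    y = np.array([0, 0, 0, 0, 1])
    Xr, yr = SMOTE(seed=0).fit_resample(X, y)
    assert (yr == 1).sum() == 4
    np.testing.assert_array_equal(Xr[5:], np.tile(X[4], (3, 1)))


def test_pipeline_scaler_statistics_come_from_resampled_training_data(toy_xy):
    X, y = toy_xy
    from sklearn.linear_model import LogisticRegression

    pipe = ResampleScalePipeline(LogisticRegression(max_iter=500), seed=5)
    pipe.fit(X, y)
    Xr, _ = SMOTE(5, 5).fit_resample(X, y)
    np.testing.assert_allclose(pipe.scaler_.mean_, Xr.mean(axis=0))
    np.testing.assert_allclose(pipe.scaler_.sd_, Xr.std(axis=0, ddof=0))


def test_pipeline_refuses_to_predict_before_fitting():
    from sklearn.linear_model import LogisticRegression

    with pytest.raises(RuntimeError):
        ResampleScalePipeline(LogisticRegression()).predict_proba(np.zeros((2, 3)))


@pytest.mark.parametrize("family", ["LR", "DT", "RF", "XGB"])
def test_tuned_models_learn_a_separable_problem(toy_xy, family):
    X, y = toy_xy
    cfg = ModelConfig(family=family, n_search_iters=2, seed=42)
    model = tune_and_fit(X, y, cfg, genes=[f"f{i}" for i in range(X.shape[1])])
    assert model.cv_auc > 0.85
    assert len(model.fold_aucs) == 5
    assert 0.0 <= model.threshold <= 1.0
    assert set(model.best_params) <= set(cfg.search_space)
    acc = (model.predict_labels(X) == y).mean()
    assert acc > 0.8


def test_neural_families_have_the_declared_depths(toy_xy):
    X, y = toy_xy
    for family, n_hidden in (("NN", 1), ("DNN", 2)):
        pipe = build_model(
            ModelConfig(family=family, seed=0),
            params={"hidden_units": 16, "dropout": 0.1, "learning_rate": 0.001,
                    "epochs": 5, "batch_size": 64},
        )
        pipe.fit(X, y)
        # input + hidden layers + single-unit output
        assert pipe.classifier.layer_sizes == [X.shape[1]] + [16] * n_hidden + [1]
        proba = pipe.predict_proba(X)
        assert proba.shape == (len(y), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)


def test_mlp_input_gradients_match_numerical_differentiation():
    rng = np.random.default_rng(3)
    X = rng.standard_normal((40, 5))
    y = (X[:, 0] - X[:, 1] > 0).astype(int)
    net = MLPBinaryClassifier(hidden_units=8, dropout=0.0, learning_rate=0.01,
                              epochs=15, batch_size=16, n_hidden_layers=2, seed=0)
    net.fit(X, y)
    g = net.input_gradients(X[:3])
    eps = 1e-6
    for i in range(3):
        for j in range(5):
            xp, xm = X[i:i + 1].copy(), X[i:i + 1].copy()
            xp[0, j] += eps
            xm[0, j] -= eps
            num = (net.predict_proba(xp)[0, 1] - net.predict_proba(xm)[0, 1]) / (2 * eps)
            assert g[i, j] == pytest.approx(num, abs=1e-6)


def test_mlp_learns_a_separable_problem(toy_xy):
    X, y = toy_xy
    net = MLPBinaryClassifier(hidden_units=32, dropout=0.1, learning_rate=0.005,
                              epochs=30, batch_size=32, n_hidden_layers=1, seed=1)
    net.fit(X, y)
    acc = ((net.predict_proba(X)[:, 1] >= 0.5).astype(int) == y).mean()
    assert acc > 0.85


def test_all_declared_families_are_constructible():
    for family in FAMILIES:
        pipe = build_model(ModelConfig(family=family, seed=0))
        assert hasattr(pipe.classifier, "fit")
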