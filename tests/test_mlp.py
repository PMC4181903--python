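"""Stratified splitting, forward pass, SCG training dynamics, and the
retraining loop."""

import numpy as np
import pandas as pd
import pytest

from sonotex.mlp import (MLPResults, SplitAssignment, TextureMLP, TrainConfig,
                         forward, predict, retrain_until, scg_train, split_data)


def make_table(X, y):
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
    df["case_id"] = [f"c{i}" for i in range(len(df))]
    df["class"] = np.where(np.asarray(y) == 1, "abnormal", "normal")
    return df


def gaussian_cluster_table(seed, n_per_class=30, sep=3.0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 1.0, size=(n_per_class, 4))
    X1 = rng.normal(sep, 1.0, size=(n_per_class, 4))
    X = np.vstack([X0, X1])
    y = np.repeat([0, 1], n_per_class)
    return make_table(X, y)


def xor_model():
    X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
    y = np.array([0, 1, 1, 0])
    return TextureMLP(X, y, n_hidden=4)


# -- split_data -------------------------------------------------------------

def test_split_60_cases_gives_48_6_6_stratified():
    table = gaussian_cluster_table(0)
    split = split_data(table, (0.8, 0.1, 0.1), seed=1)
    counts = pd.Series(split.labels).value_counts()
    assert counts["train"] == 48 and counts["validation"] == 6 and counts["test"] == 6
    y = table["class"].to_numpy()
    for part, expected in (("train", 24), ("validation", 3), ("test", 3)):
        idx = split.indices(part)
        assert np.sum(y[idx] == "abnormal") == expected


def test_split_all_train():
    table = gaussian_cluster_table(1)
    split = split_data(table, (1.0, 0.0, 0.0), seed=0)
    assert np.all(split.labels == "train")


def test_split_deterministic():
    table = gaussian_cluster_table(2)
    a = split_data(table, seed=5)
    b = split_data(table, seed=5)
    assert np.array_equal(a.labels, b.labels)


def test_split_infeasible_proportions_rejected():
    table = gaussian_cluster_table(3, n_per_class=4)
    with pytest.raises(ValueError):
        split_data(table, (0.9, 0.05, 0.05), seed=0)


# -- forward ----------------------------------------------------------------

def test_zero_weights_give_half_half():
    table = gaussian_cluster_table(4)
    res = scg_train(table, split_data(table, seed=0),
                    TrainConfig(max_epochs=1, seed=0))
    res.weights[:] = 0.0
    s = forward(res, np.zeros(4))
    assert s == (0.5, 0.5)


def test_forward_matches_hand_computed_nested_sigmoids():
    def sig(z):
        return 1.0 / (1.0 + np.exp(-z))

    model = TextureMLP(np.array([[-1.0], [1.0]]), np.array([0, 1]), n_hidden=1)
    # parameter vector: W1=[0.7], b1=[-0.2], W2=[[0.5],[-0.3]], b2=[0.1,0.4]
    w = np.array([0.7, -0.2, 0.5, -0.3, 0.1, 0.4])
    split = SplitAssignment(np.array(["train", "train"], dtype=object),
                            (1.0, 0.0, 0.0), seed=0)
    res = MLPResults(model=model, weights=w,
                     normalization=(np.array([-1.0]), np.array([1.0])),
                     split=split, config=TrainConfig(n_hidden=1),
                     trace=pd.DataFrame([{"epoch": 0, "train_mse": 0.0}]),
                     stop_reason="max_epochs", epochs_run=0)
    x = 0.3
    a = sig(0.7 * x - 0.2)
    expected = (sig(0.5 * a + 0.1), sig(-0.3 * a + 0.4))
    assert forward(res, np.array([x])) == pytest.approx(expected, abs=1e-12)


def test_normalization_minima_map_to_minus_one():
    table = gaussian_cluster_table(5)
    res = scg_train(table, split_data(table, seed=0),
                    TrainConfig(max_epochs=1, seed=0))
    lo, hi = res.normalization
    assert np.allclose(res._normalize(lo[None, :]), -1.0)
    assert np.allclose(res._normalize(hi[None, :]), 1.0)


def test_feature_count_mismatch_rejected():
    table = gaussian_cluster_table(6)
    res = scg_train(table, split_data(table, seed=0),
                    TrainConfig(max_epochs=1, seed=0))
    with pytest.raises(ValueError):
        res.scores(np.zeros((1, 7)))


# -- SCG training -----------------------------------------------------------

def test_backprop_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(10, 5))
    y = rng.integers(0, 2, 10)
    m = TextureMLP(X, y, n_hidden=3)
    w = rng.uniform(-0.5, 0.5, m._n_params())
    Xn = np.clip(X, -1, 1)
    T = np.column_stack([1.0 - y, y]).astype(float)
    g = m._grad(w, Xn, T)
    eps = 1e-5
    gfd = np.empty_like(w)
    for i in range(w.size):
        wp, wm = w.copy(), w.copy()
        wp[i] += eps
        wm[i] -= eps
        gfd[i] = (m._loss(wp, Xn, T) - m._loss(wm, Xn, T)) / (2 * eps)
    rel = np.abs(g - gfd) / np.maximum(np.abs(gfd), 1e-8)
    assert rel.max() < 1e-6


def test_xor_trains_below_mse_001_within_500_epochs():
    res = xor_model().fit(config=TrainConfig(seed=1, max_epochs=500))
    assert res.final_mse < 0.01
    assert res.epochs_run <= 500


def test_first_scg_step_does_not_increase_train_mse():
    res = xor_model().fit(config=TrainConfig(seed=1, max_epochs=1))
    mse = res.trace["train_mse"].to_numpy()
    assert mse[-1] <= mse[0]


def test_final_train_mse_never_exceeds_initial():
    table = gaussian_cluster_table(7)
    split = split_data(table, seed=0)
    for seed in range(5):
        res = scg_train(table, split, TrainConfig(seed=seed))
        mse = res.trace["train_mse"].to_numpy()
        assert mse[-1] <= mse[0]


def test_training_bitwise_reproducible():
    table = gaussian_cluster_table(8)
    split = split_data(table, seed=0)
    a = scg_train(table, split, TrainConfig(seed=3))
    b = scg_train(table, split, TrainConfig(seed=3))
    assert np.array_equal(a.weights, b.weights)
    assert a.trace.equals(b.trace)


def test_degenerate_single_class_train_partition_rejected():
    X = np.random.default_rng(0).normal(size=(6, 2))
    table = make_table(X, np.zeros(6, dtype=int))
    split = SplitAssignment(np.array(["train"] * 6, dtype=object),
                            (1.0, 0.0, 0.0), seed=0)
    with pytest.raises(ValueError):
        scg_train(table, split, TrainConfig())


# -- predict / retrain ------------------------------------------------------

def test_separable_toy_reaches_perfect_training_labels():
    table = gaussian_cluster_table(9, sep=4.0)
    split = split_data(table, (1.0, 0.0, 0.0), seed=0)
    res = scg_train(table, split, TrainConfig(seed=2))
    pred = predict(res, table)
    assert np.array_equal(pred["predicted"].to_numpy(), table["class"].to_numpy())


def test_score_tie_resolves_to_abnormal():
    table = gaussian_cluster_table(10)
    res = scg_train(table, split_data(table, seed=0),
                    TrainConfig(max_epochs=1, seed=0))
    res.weights[:] = 0.0  # every score pair is exactly (0.5, 0.5)
    pred = predict(res, table)
    assert np.all(pred["predicted"] == "abnormal")


def test_predict_empty_table():
    table = gaussian_cluster_table(11)
    res = scg_train(table, split_data(table, seed=0),
                    TrainConfig(max_epochs=1, seed=0))
    out = predict(res, table.iloc[:0])
    assert len(out) == 0


def test_retrain_until_unachievable_returns_best_effort():
    table = gaussian_cluster_table(12)
    split = split_data(table, seed=0)
    res = retrain_until(table, split, TrainConfig(seed=0),
                        min_accuracy=1.01, max_restarts=3)
    assert len(res.restart_log) == 3
    assert res.validation_accuracy() == res.restart_log["validation_accuracy"].max()


def test_retrain_until_single_restart_equals_plain_training():
    table = gaussian_cluster_table(13)
    split = split_data(table, seed=0)
    a = retrain_until(table, split, TrainConfig(seed=5), min_accuracy=0.0,
                      max_restarts=1)
    b = scg_train(table, split, TrainConfig(seed=5))
    assert np.array_equal(a.weights, b.weights)


def test_well_separated_clusters_reach_90pct_test_accuracy():
    """Parameter-recovery analogue: two separated Gaussian clusters are
    classified at >= 90% held-out accuracy in >= 9/10 seeds."""
    wins = 0
    for seed in range(10):
        table = gaussian_cluster_table(100 + seed, sep=3.0)
        split = split_data(table, seed=seed)
        res = retrain_until(table, split, TrainConfig(seed=seed),
                            min_accuracy=0.9, max_restarts=3)
        ho = gaussian_cluster_table(200 + seed, n_per_class=20, sep=3.0)
        X = ho[res.model.feature_names].to_numpy(float)
        acc = np.mean(res.predict(X) == ho["class"].to_numpy())
        wins += acc >= 0.9
    assert wins >= 9


def test_model_json_roundtrip(tmp_path):
    table = gaussian_cluster_table(14)
    res = scg_train(table, split_data(table, seed=0), TrainConfig(seed=1))
    path = tmp_path / "model.json"
    res.to_json(path)
    loaded = MLPResults.from_json(path)
    X = table[res.model.feature_names].to_numpy(float)
    assert np.allclose(loaded.scores(X), res.scores(X), atol=1e-12)


def test_summary_mentions_stop_reason():
    table = gaussian_cluster_table(15)
    res = scg_train(table, split_data(table, seed=0), TrainConfig(seed=0))
    text = res.summary()
    assert "stop reason" in text and res.stop_reason in text
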