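"""Classifier zoo: training, dense-engine oracle, complexity, serialization."""

import numpy as np
import pandas as pd
import pytest

from wotrack.models import (ModelSpec, complexity, forward_dense, load_model,
                            predict_table, save_model, train)
from wotrack.nn import BN_EPS, DenseNet


def toy_table(n=300, separation=4.0, seed=0):
    """Linearly separable-ish two-class table over the 7 muscular features."""
    g = np.random.default_rng(seed)
    rows = []
    for cond, shift in (("pre", 0.0), ("post", separation)):
        X = g.normal(shift, 1.0, size=(n // 2, 7))
        for x in X:
            rows.append({"condition": cond,
                         **{f: v for f, v in zip(ModelSpec("svm").features, x)}})
    return pd.DataFrame(rows)


def reference_forward(net, x):
    """Independent dense-chain computation with explicit loops."""
    out = []
    for row in np.atleast_2d(x):
        h = [(v - m) / np.sqrt(s + BN_EPS) * g + b
             for v, m, s, g, b in zip(row, net.run_mean, net.run_var,
                                      net.gamma, net.beta)]
        for li, (w, b) in enumerate(zip(net.weights, net.biases)):
            z = [sum(h[i] * w[i][j] for i in range(len(h))) + b[j]
                 for j in range(w.shape[1])]
            if li < len(net.weights) - 1:
                act = net.activations[li]
                if act == "relu":
                    h = [max(v, 0.0) for v in z]
                elif act == "tanh":
                    h = [np.tanh(v) for v in z]
                else:
                    raise AssertionError
            else:
                h = z
        out.append(1.0 / (1.0 + np.exp(-h[0])))
    return np.array(out)


class TestShallow:
    def test_separable_svm_perfect_training_accuracy(self):
        tab = toy_table(separation=6.0)
        model = train(ModelSpec("svm"), tab, seed=0)
        pred = predict_table(model, tab)
        assert (pred["predicted"] == pred["condition"]).mean() == 1.0

    def test_knn_k_exceeds_rows(self):
        with pytest.raises(ValueError):
            train(ModelSpec("knn"), toy_table(n=10), seed=0)

    def test_knn_self_labels_with_k1(self):
        tab = toy_table(n=60, separation=2.0)
        model = train(ModelSpec("knn", knn_k=1), tab, seed=0)
        pred = predict_table(model, tab)
        assert (pred["predicted"] == pred["condition"]).all()

    def test_single_class_rejected(self):
        tab = toy_table()
        with pytest.raises(ValueError):
            train(ModelSpec("tree"), tab[tab.condition == "pre"], seed=0)

    def test_scores_in_unit_interval(self):
        tab = toy_table()
        for fam in ("tree", "qd", "svm", "knn"):
            model = train(ModelSpec(fam), tab, seed=0)
            s = model.scores(tab[list(model.spec.features)].to_numpy())
            assert (s >= 0).all() and (s <= 1).all(), fam


class TestDenseEngine:
    def test_all_zero_parameters_score_half(self):
        rng = np.random.default_rng(0)
        net = DenseNet.initialized(7, (32,), ("relu",), rng)
        for w in net.weights:
            w[:] = 0.0
        assert net.forward(np.ones(7)) == pytest.approx(0.5)

    def test_matches_reference_over_random_nets(self):
        """1000 random parameterizations vs an explicit-loop oracle, 1e-6 rel."""
        rng = np.random.default_rng(7)
        for rep in range(1000):
            hidden = tuple(rng.choice([4, 8]) for _ in range(rng.integers(1, 4)))
            acts = tuple(rng.choice(["relu", "tanh"]) for _ in hidden)
            net = DenseNet.initialized(7, hidden, acts, rng)
            net.run_mean = rng.normal(size=7)
            net.run_var = rng.uniform(0.5, 2.0, size=7)
            net.gamma = rng.normal(1, 0.2, size=7)
            net.beta = rng.normal(size=7)
            x = rng.normal(size=7)
            ours = net.forward(x)[0]
            ref = reference_forward(net, x)[0]
            assert ours == pytest.approx(ref, rel=1e-6)

    def test_sigmoid_monotone_in_final_bias(self):
        rng = np.random.default_rng(1)
        net = DenseNet.initialized(7, (8,), ("relu",), rng)
        x = rng.normal(size=7)
        scores = []
        for bias in (-5.0, 0.0, 5.0, 50.0):
            net.biases[-1][:] = bias
            scores.append(net.forward(x)[0])
        assert np.all(np.diff(scores) > 0) and scores[-1] > 0.999

    def test_dimension_mismatch(self):
        net = DenseNet.initialized(7, (8,), ("relu",), np.random.default_rng(0))
        with pytest.raises(ValueError):
            net.forward(np.ones(6))

    def test_training_is_deterministic(self):
        tab = toy_table(n=200, separation=1.0)
        a = train(ModelSpec("dnn4", max_epochs=10), tab, seed=3)
        b = train(ModelSpec("dnn4", max_epochs=10), tab, seed=3)
        x = tab[list(a.spec.features)].to_numpy()
        assert np.array_equal(forward_dense(a, x), forward_dense(b, x))

    def test_predict_table_consistent_with_forward(self):
        tab = toy_table(n=120, separation=2.0)
        model = train(ModelSpec("dnn4", max_epochs=5), tab, seed=0)
        pred = predict_table(model, tab)
        direct = forward_dense(model, tab[list(model.spec.features)].to_numpy())
        assert np.array_equal(pred["score"].to_numpy(), direct)

    def test_empty_table(self):
        tab = toy_table(n=60)
        model = train(ModelSpec("dnn4", max_epochs=2), tab, seed=0)
        out = predict_table(model, tab.iloc[:0])
        assert len(out) == 0 and "score" in out.columns


@pytest.fixture(scope="module")
def dnns():
    tab = toy_table(n=160, separation=2.0)
    return {f: train(ModelSpec(f, max_epochs=2), tab, seed=0)
            for f in ("dnn1", "dnn2", "dnn3", "dnn4")}


class TestComplexity:
    def test_single_layer_parameter_count(self):
        net = DenseNet.initialized(7, (32,), ("relu",), np.random.default_rng(0))
        assert net.weights[0].size == 7 * 32 == 224
        assert net.weights[0].size + net.biases[0].size == 256

    def test_dnn4_dense_macc(self, dnns):
        c = complexity(dnns["dnn4"])
        assert c["macc_dense"] == 7 * 32 + 32 * 1 + 33
        assert c["rom_bytes"] == 4 * c["n_params"]

    def test_capacity_ordering(self, dnns):
        p = {f: complexity(m)["n_params"] for f, m in dnns.items()}
        assert p["dnn1"] > p["dnn2"] >= p["dnn3"] > p["dnn4"]

    def test_shallow_reports_parameter_count_only(self):
        tab = toy_table(n=100)
        c = complexity(train(ModelSpec("svm"), tab, seed=0))
        assert "macc_count" not in c and c["n_params"] == 8


class TestSerialization:
    def test_round_trip_scores_identical(self, tmp_path):
        tab = toy_table(n=120, separation=2.0)
        model = train(ModelSpec("dnn3", max_epochs=5), tab, seed=1)
        path = tmp_path / "dnn3.json"
        save_model(model, path)
        loaded = load_model(path)
        x = tab[list(model.spec.features)].to_numpy()
        assert forward_dense(loaded, x) == pytest.approx(forward_dense(model, x))

    def test_shallow_refuses_serialization(self, tmp_path):
        model = train(ModelSpec("knn"), toy_table(n=100), seed=0)
        with pytest.raises(ValueError):
            save_model(model, tmp_path / "knn.json")
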