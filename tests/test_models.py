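import numpy as np
import pytest

import hsiq
from hsiq.models import (
    ArchitectureConfig,
    LSTMCellParams,
    TrainingConfig,
    build_model,
    conv_stack_lengths,
    layer_cell_params,
    lstm_cell_forward,
    predict,
    save_model,
    load_model,
    svm_fit_predict,
    train,
)
from hsiq.nn import ConvPair, Dense, LSTMLayer
from hsiq.synthetic import FUMIGATED, SUN_DRIED, SampleRecord, SyntheticConfig, simulate_dataset

CONTENTS = {"polysaccharide": 100.0, "phenol": 20.0, "so2": 50.0}


def _records(X, labels=None, so2=None):
    out = []
    for i, row in enumerate(X):
        contents = dict(CONTENTS)
        if so2 is not None:
            contents["so2"] = float(so2[i])
        out.append(SampleRecord(
            spectrum=row,
            label=labels[i] if labels is not None else SUN_DRIED,
            contents=contents,
            sample_id=f"r{i}",
        ))
    return out


def _separable_records(n=100, n_bands=32, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((n, n_bands)) * 0.1 + 0.4
    labels = np.array([FUMIGATED if i % 2 else SUN_DRIED for i in range(n)])
    X[labels == FUMIGATED, 10:16] -= 0.3  # clean class gap
    return _records(X, labels)


class TestLSTMCell:
    def _zero_params(self, hidden, n_in):
        z = lambda: np.zeros((hidden, hidden + n_in))
        b = lambda: np.zeros(hidden)
        return LSTMCellParams(W_f=z(), W_i=z(), W_g=z(), W_o=z(),
                              b_f=b(), b_i=b(), b_g=b(), b_o=b())

    def test_zero_weights_give_half_gates_and_zero_state(self):
        params = self._zero_params(3, 2)
        h, c = lstm_cell_forward(params, np.zeros(2), np.zeros(3), np.zeros(3))
        assert np.allclose(c, 0.0)
        assert np.allclose(h, 0.0)

    def test_zero_weights_halve_the_carried_cell_state(self):
        params = self._zero_params(3, 2)
        v = np.array([1.0, -2.0, 0.5])
        h, c = lstm_cell_forward(params, np.zeros(2), np.zeros(3), v)
        assert np.allclose(c, 0.5 * v)
        assert np.allclose(h, 0.5 * np.tanh(0.5 * v))

    def test_layer_matches_cell_oracle_on_random_instances(self):
        """Vectorised layer == stepwise gate equations, 100 random draws."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            hidden = int(rng.integers(2, 5))
            n_in = int(rng.integers(1, 4))
            steps = int(rng.integers(1, 6))
            layer = LSTMLayer(n_in, hidden, rng)
            params = layer_cell_params(layer)
            x = rng.normal(size=(1, steps, n_in))
            h_layer = layer.forward(x, train=False)[0]
            h = np.zeros(hidden)
            c = np.zeros(hidden)
            for t in range(steps):
                h, c = lstm_cell_forward(params, x[0, t], h, c)
            assert np.abs(h - h_layer).max() <= 1e-6

    def test_shape_mismatch_is_rejected(self):
        params = self._zero_params(3, 2)
        with pytest.raises(ValueError):
            lstm_cell_forward(params, np.zeros(5), np.zeros(3), np.zeros(3))


class TestArchitectures:
    @pytest.mark.parametrize("n_bands", [4, 100, 396])
    def test_conv_stack_shape_law(self, n_bands):
        """Output length follows floor-halving through conv/pool/conv."""
        l1, l2, l3 = conv_stack_lengths(n_bands)
        assert l1 == n_bands // 2
        assert l3 >= 1
        model = build_model(ArchitectureConfig(kind="clstm"), n_bands, seed=0)
        conv_out = None
        x = np.zeros((2, n_bands))
        for layer in model.net.layers:
            x = layer.forward(x, train=False)
            if isinstance(layer, ConvPair):
                conv_out = x.shape
        assert conv_out == (2, l3, 128)

    def test_cnn_and_clstm_share_conv_stack_parameter_shapes(self):
        cnn = build_model(ArchitectureConfig(kind="cnn"), 396, seed=0)
        clstm = build_model(ArchitectureConfig(kind="clstm"), 396, seed=0)
        conv_shapes = lambda m: [
            tuple(p.shape) for layer in m.net.layers
            if isinstance(layer, ConvPair) for p in layer.params
        ]
        assert conv_shapes(cnn) == conv_shapes(clstm)

    def test_clstm_head_widths_match_design(self):
        model = build_model(ArchitectureConfig(kind="clstm"), 396, seed=0)
        lstm = [l for l in model.net.layers if isinstance(l, LSTMLayer)][0]
        dense = [l for l in model.net.layers if isinstance(l, Dense)]
        assert lstm.hidden == 64
        assert dense[0].W.shape == (64, 128)
        assert dense[1].W.shape == (128, 2)

    def test_same_seed_reproduces_initial_parameters(self):
        a = build_model(ArchitectureConfig(kind="cnn"), 64, seed=5)
        b = build_model(ArchitectureConfig(kind="cnn"), 64, seed=5)
        for (pa, _), (pb, _) in zip(a.net.parameters(), b.net.parameters()):
            assert np.array_equal(pa, pb)

    def test_too_few_bands_is_rejected(self):
        with pytest.raises(ValueError, match="n_bands"):
            build_model(ArchitectureConfig(kind="cnn"), 2, seed=0)


class TestTraining:
    def test_separable_classes_reach_perfect_training_accuracy(self):
        records = _separable_records()
        model = build_model(
            ArchitectureConfig(kind="cnn"), n_bands=32, seed=0
        )
        train(model, records, "label",
              TrainingConfig(epochs=200, patience=0, seed=0))
        labels, probs = predict(model, records)
        acc = np.mean(labels == np.array([r.label for r in records]))
        assert acc == 1.0
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert model.history[-1] <= model.history[0]

    def test_single_epoch_yields_single_history_entry(self):
        records = _separable_records(n=20)
        model = build_model(ArchitectureConfig(kind="cnn"), 32, seed=0)
        train(model, records, "label", TrainingConfig(epochs=1, patience=0))
        assert len(model.history) == 1

    def test_regression_on_constant_target_converges_to_it(self):
        rng = np.random.default_rng(1)
        records = _records(rng.random((30, 16)), so2=np.full(30, 42.0))
        model = build_model(
            ArchitectureConfig(kind="cnn", task="regression", dropout=0.0), 16, seed=0
        )
        train(model, records, "so2",
              TrainingConfig(epochs=300, patience=0, seed=0))
        pred = predict(model, records)
        assert np.sqrt(np.mean((pred - 42.0) ** 2)) <= 1e-2

    def test_single_class_classification_is_rejected(self):
        records = _records(np.random.default_rng(0).random((10, 16)))
        model = build_model(ArchitectureConfig(kind="cnn"), 16, seed=0)
        with pytest.raises(ValueError, match="class"):
            train(model, records, "label", TrainingConfig(epochs=1))

    def test_band_count_mismatch_is_rejected_at_predict(self):
        records = _separable_records(n=20)
        model = build_model(ArchitectureConfig(kind="cnn"), 32, seed=0)
        train(model, records, "label", TrainingConfig(epochs=1, patience=0))
        short = _records(np.random.default_rng(0).random((3, 10)))
        with pytest.raises(ValueError, match="bands"):
            predict(model, short)

    def test_task_target_mismatch_is_rejected(self):
        records = _separable_records(n=20)
        model = build_model(
            ArchitectureConfig(kind="cnn", task="regression"), 32, seed=0
        )
        with pytest.raises(ValueError, match="classification"):
            train(model, records, "label", TrainingConfig(epochs=1))

    def test_lstm_model_trains_on_chunked_spectrum(self):
        records = _separable_records(n=40)
        model = build_model(ArchitectureConfig(kind="lstm"), 32, seed=0)
        train(model, records, "label",
              TrainingConfig(epochs=60, patience=0, seed=0))
        labels, _ = predict(model, records)
        assert np.mean(labels == np.array([r.label for r in records])) >= 0.9

    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path):
        records = _separable_records(n=30)
        model = build_model(ArchitectureConfig(kind="clstm"), 32, seed=0)
        train(model, records, "label", TrainingConfig(epochs=5, patience=0))
        _, probs = predict(model, records)
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        _, probs2 = predict(back, records)
        assert np.allclose(probs, probs2)


class TestSVM:
    def test_separable_toy_is_classified_perfectly(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [1.0, 1.0], [0.9, 1.0]])
        labels = np.array([SUN_DRIED, SUN_DRIED, FUMIGATED, FUMIGATED])
        records = _records(X, labels)
        pred = svm_fit_predict(records, records, "label")
        assert np.array_equal(pred, labels)

    def test_linear_target_regression_is_tight(self):
        rng = np.random.default_rng(0)
        X = rng.random((80, 4))
        y = 0.3 + 0.5 * X[:, 0]
        records = _records(X, so2=y)
        pred = svm_fit_predict(records[:60], records[60:], "so2",
                               kernel="linear", epsilon=0.01)
        rmse = np.sqrt(np.mean((pred - y[60:]) ** 2))
        assert rmse <= 0.05

    def test_single_class_training_is_rejected(self):
        records = _records(np.random.default_rng(0).random((6, 3)))
        with pytest.raises(ValueError, match="single-class"):
            svm_fit_predict(records, records, "label")

    def test_constant_features_give_constant_prediction(self):
        records = _records(np.ones((10, 3)), so2=np.arange(10.0))
        pred = svm_fit_predict(records, records, "so2")
        assert np.ptp(pred) <= 1e-8
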