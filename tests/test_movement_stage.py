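import numpy as np
import pytest

from anklemg._nn import Adam, CnnLstmNet, cross_entropy_loss
from anklemg.features import FeatureTensor
from anklemg.load_stage import LoadClassifier
from anklemg.movement_stage import (
    CnnLstmClassifier,
    ModelSpec,
    TwoStepClassifier,
    build_model,
    cross_entropy,
    tensor_to_steps,
    train_movement,
    window_to_raw_steps,
)
from anklemg.preprocessing import LargeWindow
from anklemg.synthetic_data import LOADS, MOVEMENTS

FEATURES_LAYERS = {
    "Conv1D_1": 704, "Conv1D_2": 704, "Conv1D_3": 704, "Conv1D_4": 704,
    "Conv1D_5": 2080, "Conv1D_6": 2080, "Conv1D_7": 2080, "Conv1D_8": 2080,
    "LSTM": 138_200, "Dense_1": 5100, "Dense_2": 606,
}
RAW_LAYERS = {
    "Conv1D_1": 128, "Conv1D_2": 128, "Conv1D_3": 128, "Conv1D_4": 128,
    "Conv1D_5": 2080, "Conv1D_6": 2080, "Conv1D_7": 2080, "Conv1D_8": 2080,
    "LSTM": 317_400, "Dense_1": 5100, "Dense_2": 606,
}


class TestParameterAccounting:
    @pytest.mark.parametrize(
        "mode,total,expected",
        [("features", 155_042, FEATURES_LAYERS), ("raw", 331_938, RAW_LAYERS)],
    )
    def test_layer_table(self, mode, total, expected):
        spec = ModelSpec(input_mode=mode, n_features=7)
        table = {r.name: r.n_params for r in spec.layer_table()}
        for name, n in expected.items():
            assert table[name] == n, name
        assert spec.total_params() == total

    def test_output_shapes_features_mode(self):
        spec = ModelSpec(n_features=7)
        shapes = {r.name: r.output_shape for r in spec.layer_table()}
        assert shapes["Conv1D_1"] == (10, 32)
        assert shapes["Maxpooling1D_1"] == (5, 32)
        assert shapes["Flatten_1"] == (160,)
        assert shapes["Concatenate"] == (640,)
        assert shapes["LSTM"] == (50,)
        assert shapes["Dense_2"] == (6,)

    def test_raw_mode_pooled_length_floors(self):
        spec = ModelSpec(input_mode="raw")
        shapes = {r.name: r.output_shape for r in spec.layer_table()}
        assert shapes["Conv1D_1"] == (25, 32)
        assert shapes["Maxpooling1D_1"] == (12, 32)
        assert shapes["Concatenate"] == (1536,)

    @pytest.mark.parametrize("mode", ["features", "raw"])
    def test_network_arrays_match_closed_form(self, mode):
        """The actual parameter arrays of the instantiated net must sum to the
        declarative layer-table counts, per block."""
        spec = ModelSpec(input_mode=mode, n_features=7)
        model = build_model(spec)
        net = CnnLstmNet(in_len=spec.in_len, in_feat=spec.in_feat)
        conv1 = sum(net.params[f"W1_{c}"].size + net.params[f"b1_{c}"].size for c in range(4))
        conv2 = sum(net.params[f"W2_{c}"].size + net.params[f"b2_{c}"].size for c in range(4))
        table = {r.name: r.n_params for r in model.layer_table()}
        assert conv1 == 4 * table["Conv1D_1"]
        assert conv2 == 4 * table["Conv1D_5"]
        lstm = net.params["Wx"].size + net.params["Wh"].size + net.params["b_lstm"].size
        assert lstm == table["LSTM"]
        assert net.n_parameters() == model.total_parameters()

    def test_degenerate_pooling_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(step_len=1, pool=2)


class TestCrossEntropy:
    def test_one_hot_correct_is_zero(self):
        probs = np.eye(6)[[0, 3, 5]]
        assert cross_entropy(probs, [0, 3, 5]) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_is_log_six(self):
        probs = np.full((4, 6), 1 / 6)
        assert cross_entropy(probs, [0, 1, 2, 3]) == pytest.approx(np.log(6), abs=1e-9)

    def test_half_quarter_batch(self):
        probs = np.array([[0.5] + [0.1] * 5, [0.25] + [0.15] * 5])
        assert cross_entropy(probs, [0, 0]) == pytest.approx(
            (np.log(2) + np.log(4)) / 2, abs=1e-4
        )

    def test_rows_must_be_distributions(self):
        with pytest.raises(ValueError):
            cross_entropy(np.ones((2, 6)), [0, 1])


class TestStepSplitting:
    def test_shape_and_slicing_identity(self):
        rng = np.random.default_rng(0)
        t = FeatureTensor(rng.standard_normal((20, 7, 4)), feature_names=tuple("abcdefg"))
        steps = tensor_to_steps(t)
        assert steps.shape == (2, 4, 10, 7)
        np.testing.assert_array_equal(steps[0, 2], t.values[:10, :, 2])
        np.testing.assert_array_equal(steps[1, 2], t.values[10:, :, 2])

    def test_concatenation_reconstructs_tensor(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((20, 7, 4))
        steps = tensor_to_steps(values)
        rebuilt = np.concatenate(
            [steps[0].transpose(1, 2, 0), steps[1].transpose(1, 2, 0)], axis=0
        )
        np.testing.assert_array_equal(rebuilt, values)

    def test_wrong_subwindow_count_rejected(self):
        with pytest.raises(ValueError):
            tensor_to_steps(np.zeros((18, 7, 4)))

    def test_raw_window_conversion(self):
        rng = np.random.default_rng(2)
        steps = window_to_raw_steps(rng.standard_normal((4, 210)))
        assert steps.shape == (2, 4, 25, 1)


class TestGradientsAndTraining:
    def test_backward_matches_finite_differences(self):
        net = CnnLstmNet(in_len=6, in_feat=3, n_channels=2, lstm_units=4,
                         dense_units=5, conv_filters=3, dropout=0.0, seed=1)
        rng = np.random.default_rng(0)
        for v in net.params.values():  # move ReLU kinks off exact zero
            v += rng.normal(0, 0.05, v.shape)
        X = rng.standard_normal((5, 2, 2, 6, 3))
        y = rng.integers(0, 6, 5)
        _, cache = net.forward(X)
        grads = net.backward(cache, y)
        eps = 1e-6
        for k, v in net.params.items():
            flat, g = v.ravel(), grads[k].ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = cross_entropy_loss(net.forward(X)[0], y)
                flat[i] = old - eps
                lm = cross_entropy_loss(net.forward(X)[0], y)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert g[i] == pytest.approx(num, rel=1e-3, abs=1e-7), k

    def test_softmax_rows_sum_to_one(self):
        net = CnnLstmNet(in_len=10, in_feat=7, seed=0)
        X = np.random.default_rng(3).standard_normal((8, 2, 4, 10, 7))
        probs, _ = net.forward(X)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_loss_decreases_on_random_task(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((512, 20, 7, 4))
        y = rng.integers(0, 6, 512)
        # give labels structure so there is something to fit
        X[np.arange(512), 0, 0, 0] += 3.0 * y
        model = CnnLstmClassifier(epochs=3, random_state=0)
        model.fit(X, y)
        assert model.history_[-1] < model.history_[0]

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((64, 20, 7, 4))
        y = rng.integers(0, 6, 64)
        h1 = CnnLstmClassifier(epochs=2, random_state=9).fit(X, y).history_
        h2 = CnnLstmClassifier(epochs=2, random_state=9).fit(X, y).history_
        assert h1 == h2

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            CnnLstmClassifier().fit(np.zeros((0, 20, 7, 4)), np.array([]))

    def test_train_movement_wrapper_sets_epochs(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((32, 20, 7, 4))
        y = rng.integers(0, 6, 32)
        model = train_movement(CnnLstmClassifier(), X, y, epochs=2, seed=1)
        assert len(model.history_) == 2


class TestPersistence:
    def test_movement_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((48, 20, 7, 4))
        y = rng.integers(0, 6, 48)
        model = CnnLstmClassifier(epochs=2, random_state=3).fit(X, y)
        model.save(tmp_path / "move")
        loaded = CnnLstmClassifier.load(tmp_path / "move")
        np.testing.assert_allclose(
            loaded.predict_proba(X), model.predict_proba(X), atol=1e-12
        )
        assert loaded.total_parameters() == 155_042

    def test_load_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        X = np.abs(rng.normal(50, 20, (60, 4)))
        y = np.array([LOADS[i % 3] for i in range(60)])
        model = LoadClassifier(n_trees=20, random_state=0).fit(X, y)
        model.save(tmp_path / "load_model.joblib")
        loaded = LoadClassifier.load(tmp_path / "load_model.joblib")
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))


class TestTwoStep:
    def _fitted_models(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((60, 20, 7, 4))
        y = rng.integers(0, 6, 60)
        m = CnnLstmClassifier(epochs=1, random_state=seed).fit(X, y)
        rms = np.abs(rng.normal(50, 10, (60, 4)))
        loads = np.array([LOADS[i % 3] for i in range(60)])
        load_clf = LoadClassifier(n_trees=20, random_state=0).fit(rms, loads)
        return m, load_clf, X, rms

    def test_identical_models_reduce_to_one_step(self):
        m, load_clf, X, rms = self._fitted_models()
        clf = TwoStepClassifier(load_clf, {l: m for l in LOADS})
        np.testing.assert_array_equal(clf.predict(X, rms=rms), m.predict(X))

    def test_predictions_in_label_range(self):
        m, load_clf, X, rms = self._fitted_models(seed=1)
        clf = TwoStepClassifier(load_clf, {l: m for l in LOADS})
        pred = clf.predict(X, rms=rms)
        assert set(np.unique(pred)) <= set(range(6))

    def test_missing_load_model_rejected(self):
        m, load_clf, _, _ = self._fitted_models()
        with pytest.raises(ValueError, match="missing movement model"):
            TwoStepClassifier(load_clf, {"low": m, "medium": m})

    def test_single_window_prediction_returns_movement_name(self):
        from anklemg.features import FeatureSpec
        from anklemg.movement_stage import two_step_predict

        m, load_clf, _, _ = self._fitted_models(seed=2)
        seven = FeatureSpec(names=("RMS", "MAV", "WL", "ZC", "SSC", "VAR", "LogD"))
        clf = TwoStepClassifier(load_clf, {l: m for l in LOADS}, feature_spec=seven)
        rng = np.random.default_rng(0)
        win = LargeWindow(rng.normal(0, 50, (4, 210)), fs=1000.0)
        assert two_step_predict(clf, win) in MOVEMENTS
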