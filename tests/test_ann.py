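"""MLP surrogate: initialization, gradients, training, search, prediction."""

import numpy as np
import pytest

from printopt.ann import (
    MLPConfig,
    NN1_CONFIG,
    NN2_CONFIG,
    architecture_search,
    forward,
    init_mlp,
    load_mlp,
    loss_and_gradients,
    predict_release,
    save_mlp,
    train_backprop,
)
from printopt.data import Formulation


def _finite_difference_grads(mlp, Xs, Ys, eps=1e-6):
    """Central differences through every weight and bias entry."""
    num_W, num_b = [], []
    for layer in range(len(mlp.weights)):
        gW = np.zeros_like(mlp.weights[layer])
        for idx in np.ndindex(*mlp.weights[layer].shape):
            orig = mlp.weights[layer][idx]
            mlp.weights[layer][idx] = orig + eps
            up = loss_and_gradients(mlp, Xs, Ys)[0]
            mlp.weights[layer][idx] = orig - eps
            down = loss_and_gradients(mlp, Xs, Ys)[0]
            mlp.weights[layer][idx] = orig
            gW[idx] = (up - down) / (2 * eps)
        num_W.append(gW)
        gb = np.zeros_like(mlp.biases[layer])
        for idx in np.ndindex(*mlp.biases[layer].shape):
            orig = mlp.biases[layer][idx]
            mlp.biases[layer][idx] = orig + eps
            up = loss_and_gradients(mlp, Xs, Ys)[0]
            mlp.biases[layer][idx] = orig - eps
            down = loss_and_gradients(mlp, Xs, Ys)[0]
            mlp.biases[layer][idx] = orig
            gb[idx] = (up - down) / (2 * eps)
        num_b.append(gb)
    return num_W, num_b


class TestInit:
    def test_same_seed_identical_weights(self):
        a = init_mlp(NN1_CONFIG)
        b = init_mlp(NN1_CONFIG)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_different_seed_different_weights(self):
        a = init_mlp(NN1_CONFIG)
        b = init_mlp(MLPConfig(layer_sizes=(3, 8, 5),
                               activations=("linear", "linear"), seed=99))
        assert not np.array_equal(a.weights[0], b.weights[0])

    def test_shapes_match_architecture(self):
        mlp = init_mlp(NN1_CONFIG)
        assert [W.shape for W in mlp.weights] == [(3, 8), (8, 5)]
        deep = init_mlp(NN2_CONFIG)
        assert [W.shape for W in deep.weights] == [
            (4, 5), (5, 5), (5, 6), (6, 5), (5, 6), (6, 4)
        ]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MLPConfig(layer_sizes=(3,), activations=())
        with pytest.raises(ValueError):
            MLPConfig(layer_sizes=(3, 5), activations=("tanh",))


class TestForwardAndGradients:
    def test_zero_network_outputs_zero_on_scaled_scale(self):
        mlp = init_mlp(NN1_CONFIG)
        for W in mlp.weights:
            W[:] = 0.0
        for b in mlp.biases:
            b[:] = 0.0
        out = forward(mlp, np.array([50.0, 30.0, 15.0]))
        np.testing.assert_array_equal(out, np.zeros(5))

    @pytest.mark.parametrize("depth", [1, 2, 3, 4, 5])
    @pytest.mark.parametrize("activation", ["linear", "log_sigmoid"])
    def test_backprop_matches_central_differences(self, depth, activation):
        rng = np.random.default_rng(100 * depth + len(activation))
        sizes = (3,) + (4,) * depth + (2,)
        cfg = MLPConfig(
            layer_sizes=sizes,
            activations=(activation,) * depth + ("linear",),
            seed=depth,
        )
        mlp = init_mlp(cfg)
        Xs = rng.uniform(0, 1, size=(6, 3))
        Ys = rng.uniform(0, 1, size=(6, 2))
        _, gW, gb = loss_and_gradients(mlp, Xs, Ys)
        num_W, num_b = _finite_difference_grads(mlp, Xs, Ys)
        for a, n in zip(gW + gb, num_W + num_b):
            np.testing.assert_allclose(a, n, rtol=1e-6, atol=1e-9)


class TestTraining:
    def test_all_linear_network_reaches_least_squares_minimum(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 100, size=(12, 3))
        A = np.array([[0.5, -0.2], [0.1, 0.4], [0.3, 0.3]])
        Y = X @ A + 5.0
        cfg = MLPConfig(
            layer_sizes=(3, 4, 2), activations=("linear", "linear"),
            learning_rate=0.2, momentum=0.6, max_epochs=20000, patience=2000,
            seed=0,
        )
        mlp, _ = train_backprop(init_mlp(cfg), X, Y)
        # closed-form least squares on the same scaled problem
        Xs = (X - mlp.x_min) / mlp.x_range
        Ys = (Y - mlp.y_min) / mlp.y_range
        Xa = np.column_stack([Xs, np.ones(len(Xs))])
        beta, *_ = np.linalg.lstsq(Xa, Ys, rcond=None)
        resid = Ys - Xa @ beta
        optimum = 0.5 * float(np.mean(resid**2))
        final = loss_and_gradients(mlp, Xs, Ys)[0]
        assert final == pytest.approx(optimum, abs=1e-6)

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        cfg = MLPConfig(
            layer_sizes=(3, 8, 5), activations=("linear", "linear"),
            learning_rate=0.0, max_epochs=50, patience=10, seed=1,
        )
        mlp = init_mlp(cfg)
        before = [W.copy() for W in mlp.weights]
        rng = np.random.default_rng(0)
        train_backprop(mlp, rng.uniform(0, 1, (5, 3)), rng.uniform(0, 1, (5, 5)))
        for W0, W1 in zip(before, mlp.weights):
            np.testing.assert_array_equal(W0, W1)

    def test_training_loss_nonincreasing_at_small_rate_without_momentum(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(0, 1, size=(10, 3))
        Y = X @ np.array([[1.0], [0.5], [-0.2]])
        cfg = MLPConfig(
            layer_sizes=(3, 4, 1), activations=("linear", "linear"),
            learning_rate=0.01, momentum=0.0, max_epochs=500, patience=500,
            seed=2,
        )
        mlp, _ = train_backprop(init_mlp(cfg), X, Y)
        history = np.array(mlp.training_history)
        assert np.all(np.diff(history) <= 1e-12)

    def test_identical_seeds_and_data_give_identical_history(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 100, (8, 3))
        Y = rng.uniform(0, 100, (8, 5))
        cfg = MLPConfig(
            layer_sizes=(3, 8, 5), activations=("linear", "linear"),
            learning_rate=0.1, max_epochs=200, patience=50, seed=3,
        )
        a, _ = train_backprop(init_mlp(cfg), X, Y)
        b, _ = train_backprop(init_mlp(cfg), X, Y)
        assert a.training_history == b.training_history

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_raises_with_epoch_index(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (6, 3)) * 1e6
        Y = rng.uniform(0, 1, (6, 2)) * 1e6
        cfg = MLPConfig(
            layer_sizes=(3, 4, 2), activations=("linear", "linear"),
            learning_rate=1.0, momentum=1.0, max_epochs=5000, patience=5000,
            seed=4,
        )
        mlp = init_mlp(cfg)
        # un-scaled targets far outside [0,1] with maximal rate+momentum
        mlp.x_range[:] = 1e-6
        with pytest.raises(FloatingPointError, match="epoch"):
            train_backprop(mlp, X, Y)


class TestArchitectureSearch:
    @staticmethod
    def _toy_data(seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 100, (10, 3))
        Y = X @ np.array([[0.3, 0.5], [0.2, 0.1], [0.4, 0.2]])
        return X[:8], Y[:8], X[8:], Y[8:]

    def test_leaderboard_covers_the_grid_and_is_deterministic(self):
        Xt, Yt, Xv, Yv = self._toy_data()
        template = MLPConfig(
            layer_sizes=(3, 4, 2), activations=("linear", "linear"),
            learning_rate=0.1, max_epochs=300, patience=50, seed=5,
        )
        _, _, board_a = architecture_search(
            Xt, Yt, Xv, Yv, hidden_layer_counts=(1, 2),
            nodes_per_layer=(4, 5), template=template,
        )
        _, _, board_b = architecture_search(
            Xt, Yt, Xv, Yv, hidden_layer_counts=(1, 2),
            nodes_per_layer=(4, 5), template=template,
        )
        assert len(board_a) == 4
        assert board_a == board_b

    def test_depth_does_not_help_on_linear_data(self):
        Xt, Yt, Xv, Yv = self._toy_data(seed=1)
        template = MLPConfig(
            layer_sizes=(3, 4, 2), activations=("linear", "linear"),
            learning_rate=0.1, max_epochs=2000, patience=500, seed=6,
        )
        _, _, board = architecture_search(
            Xt, Yt, Xv, Yv, hidden_layer_counts=(1, 3),
            nodes_per_layer=(6,), template=template,
        )
        shallow = next(r for r in board if r["hidden_layers"] == 1)
        deep = next(r for r in board if r["hidden_layers"] == 3)
        # deeper all-linear nets share the hypothesis class of the shallow one
        assert deep["rms"] >= shallow["rms"] - 0.02


class TestPredictRelease:
    def test_composition_network_returns_five_points(self):
        mlp = init_mlp(NN1_CONFIG, times=(1, 2, 4, 6, 8))
        f = Formulation("x", 50.0, 30.0, 14.9)
        out = predict_release(mlp, f)
        assert out.shape == (5,)
        assert np.all((out >= 0) & (out <= 100))

    def test_exposure_time_required_for_four_input_network(self):
        mlp = init_mlp(NN2_CONFIG, times=(2, 4, 6, 8))
        f = Formulation("x", 50.0, 30.0, 14.9)
        with pytest.raises(ValueError, match="exposure_time"):
            predict_release(mlp, f)
        out = predict_release(mlp, f, exposure_time=500.0)
        assert out.shape == (4,)

    def test_predictions_clip_to_0_100(self):
        mlp = init_mlp(NN1_CONFIG, times=(1, 2, 4, 6, 8))
        mlp.y_min = np.full(5, -500.0)
        mlp.y_range = np.full(5, 1000.0)
        out = predict_release(mlp, Formulation("x", 50.0, 30.0, 14.9))
        assert np.all((out >= 0.0) & (out <= 100.0))

    def test_save_load_round_trip(self, tmp_path):
        mlp = init_mlp(NN1_CONFIG, times=(1, 2, 4, 6, 8))
        path = tmp_path / "model.json"
        save_mlp(mlp, path)
        loaded = load_mlp(path)
        f = Formulation("x", 40.0, 40.0, 14.9)
        np.testing.assert_allclose(
            predict_release(mlp, f), predict_release(loaded, f), rtol=1e-12
        )
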