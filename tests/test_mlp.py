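import numpy as np
import pytest

from nirtaste.errors import ConfigError, RegistryError, ShapeError
from nirtaste.mlp import (
    MLPArchitecture,
    TrainingConfig,
    init_mlp,
    predict,
    train_mlp,
    transfer_apply,
)


class TestTransferRegistry:
    @pytest.mark.parametrize(
        "name, x, expected",
        [
            ("tansig", 0.0, 0.0),
            ("logsig", 0.0, 0.5),
            ("purelin", 2.5, 2.5),
            ("tribas", 0.0, 1.0),
            ("poslin", -1.0, 0.0),
            ("radbas", 0.0, 1.0),
            ("tansig", 1.0, 0.7615941559557649),  # tanh(1) to double precision
            ("satlin", 0.4, 0.4),
            ("satlins", -3.0, -1.0),
            ("hardlim", -0.1, 0.0),
            ("hardlims", -0.1, -1.0),
            ("elliotsig", 1.0, 0.5),
        ],
    )
    def test_values(self, name, x, expected):
        assert transfer_apply(name, x) == pytest.approx(expected, abs=1e-12)

    def test_tansig_matches_formula(self):
        x = np.linspace(-3, 3, 11)
        np.testing.assert_allclose(transfer_apply("tansig", x),
                                   2.0 / (1.0 + np.exp(-2 * x)) - 1.0, atol=1e-12)

    def test_radbasn_normalises_layer(self):
        out = transfer_apply("radbasn", np.array([[0.0, 1.0, 2.0]]))
        assert out.sum() == pytest.approx(1.0)

    def test_unknown_name_lists_registry(self):
        with pytest.raises(RegistryError, match="tansig"):
            transfer_apply("sigmoid", 0.0)


class TestArchitecture:
    def test_layer_bounds(self):
        with pytest.raises(ConfigError):
            MLPArchitecture(neurons=(0,), transfer=("tansig",))
        with pytest.raises(ConfigError):
            MLPArchitecture(neurons=(26,), transfer=("tansig",))

    def test_zero_layer_cascade(self):
        with pytest.raises(ConfigError):
            MLPArchitecture(neurons=(5, 0, 3), transfer=("tansig",) * 3)

    def test_unknown_trainer(self):
        with pytest.raises(RegistryError):
            MLPArchitecture(neurons=(5,), transfer=("tansig",), train_fn="trainlm")

    def test_json_round_trip(self):
        arch = MLPArchitecture(neurons=(19, 13, 16),
                               transfer=("tribas", "poslin", "tansig"),
                               train_fn="trainbr", learn_fn="learngd")
        assert MLPArchitecture.from_dict(arch.to_dict()) == arch


class TestInit:
    def test_deterministic(self):
        arch = MLPArchitecture(neurons=(4,), transfer=("tansig",))
        a = init_mlp(arch, 3, seed=7)
        b = init_mlp(arch, 3, seed=7)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_three_layer_shapes(self):
        """19/13/16 hidden layers give weight shapes ending in a single output."""
        arch = MLPArchitecture(neurons=(19, 13, 16),
                               transfer=("tribas", "poslin", "tansig"),
                               train_fn="trainbr")
        net = init_mlp(arch, 3, seed=0)
        assert [w.shape for w in net.weights] == [(3, 19), (19, 13), (13, 16), (16, 1)]

    def test_two_layer_shapes(self):
        arch = MLPArchitecture(neurons=(21, 9), transfer=("radbas", "tansig"),
                               train_fn="traingd")
        net = init_mlp(arch, 5, seed=0)
        assert len(net.weights) == 3
        assert net.weights[-1].shape == (9, 1)


def _linear_data(rng, n=120, p=2):
    X = rng.uniform(-1, 1, (n, p))
    y = X @ np.arange(1, p + 1) + 0.5
    return X, y


class TestTraining:
    def test_traingd_fits_linear_target(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (100, 1))
        y = 2 * X[:, 0]
        arch = MLPArchitecture(neurons=(1,), transfer=("purelin",), train_fn="traingd")
        cfg = TrainingConfig(max_epochs=2000, val_patience=2000, learning_rate=0.1)
        net = train_mlp(init_mlp(arch, 1, 0), X[:60], y[:60], X[60:], y[60:], cfg)
        assert np.mean((predict(net, X[60:]) - y[60:]) ** 2) < 1e-4

    def test_zero_epochs_returns_initial_weights(self):
        rng = np.random.default_rng(1)
        X, y = _linear_data(rng)
        arch = MLPArchitecture(neurons=(3,), transfer=("tansig",), train_fn="trainrp")
        net0 = init_mlp(arch, 2, seed=3)
        net = train_mlp(net0, X, y, cfg=TrainingConfig(max_epochs=0))
        for w0, w1 in zip(net0.weights, net.weights):
            np.testing.assert_array_equal(w0, w1)

    def test_trainrp_learns_product_surface(self):
        """Smooth XOR-like target y = x1*x2; reference nets reach ~1e-3 MSE."""
        rng = np.random.default_rng(2)
        X = rng.uniform(-1, 1, (400, 2))
        y = X[:, 0] * X[:, 1]
        arch = MLPArchitecture(neurons=(8,), transfer=("tansig",), train_fn="trainrp")
        cfg = TrainingConfig(max_epochs=2000, val_patience=300)
        net = train_mlp(init_mlp(arch, 2, 1), X[:300], y[:300], X[300:350], y[300:350], cfg)
        assert np.mean((predict(net, X[350:]) - y[350:]) ** 2) < 0.01

    @pytest.mark.parametrize("trainer", ["traingd", "traingdm", "trainrp"])
    def test_bitwise_determinism(self, trainer):
        rng = np.random.default_rng(4)
        X, y = _linear_data(rng)
        arch = MLPArchitecture(neurons=(4,), transfer=("logsig",), train_fn=trainer)
        cfg = TrainingConfig(max_epochs=50, val_patience=50)
        a = train_mlp(init_mlp(arch, 2, 9), X[:80], y[:80], X[80:], y[80:], cfg)
        b = train_mlp(init_mlp(arch, 2, 9), X[:80], y[:80], X[80:], y[80:], cfg)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_purelin_bfgs_matches_least_squares(self):
        """A linear-transfer network at convergence equals the OLS solution."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + 0.3 + 0.05 * rng.normal(size=60)
        arch = MLPArchitecture(neurons=(4, 2), transfer=("purelin", "purelin"),
                               train_fn="trainbfg")
        net = train_mlp(init_mlp(arch, 3, 2), X, y, cfg=TrainingConfig(max_epochs=500))
        design = np.column_stack([X, np.ones(60)])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        ols_mse = np.mean((design @ beta - y) ** 2)
        assert np.mean((predict(net, X) - y) ** 2) == pytest.approx(ols_mse, abs=1e-6)

    def test_early_stopping_keeps_best_validation_epoch(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-1, 1, (60, 2))
        y = X[:, 0] + 0.3 * rng.normal(size=60)  # noisy: overfitting possible
        arch = MLPArchitecture(neurons=(12,), transfer=("tansig",), train_fn="trainrp")
        cfg = TrainingConfig(max_epochs=500, val_patience=30)
        net = train_mlp(init_mlp(arch, 2, 0), X[:40], y[:40], X[40:], y[40:], cfg)
        val_trace = [v for (_, _, v) in net.trace]
        best = min(val_trace)
        stopped_val = net.trace[net.stopped_epoch - 1][2]
        assert stopped_val == pytest.approx(best)
        achieved = np.mean((predict(net, X[40:]) - y[40:]) ** 2)
        # returned weights realise the best-epoch validation MSE
        assert achieved == pytest.approx(best * np.var(y[:40]), rel=1e-6)

    def test_trainbr_penalises_weights(self):
        rng = np.random.default_rng(7)
        X, y = _linear_data(rng, n=80)
        arch_br = MLPArchitecture(neurons=(6,), transfer=("tansig",), train_fn="trainbr")
        cfg = TrainingConfig(max_epochs=200, val_patience=200)
        net = train_mlp(init_mlp(arch_br, 2, 0), X[:60], y[:60], X[60:], y[60:], cfg)
        assert np.mean((predict(net, X[60:]) - y[60:]) ** 2) < 0.05


class TestPredict:
    def test_zero_weights_predict_bias(self):
        arch = MLPArchitecture(neurons=(3,), transfer=("tansig",))
        net = init_mlp(arch, 2, seed=0)
        for w in net.weights:
            w[...] = 0.0
        net.biases[-1][...] = 1.25
        np.testing.assert_allclose(predict(net, np.zeros((4, 2))), np.full(4, 1.25))

    def test_hand_computed_single_unit(self):
        """Forward pass checked against pencil-and-paper arithmetic."""
        arch = MLPArchitecture(neurons=(1,), transfer=("tansig",))
        net = init_mlp(arch, 1, seed=0)
        net.weights[0][...] = [[2.0]]
        net.biases[0][...] = [0.5]
        net.weights[1][...] = [[3.0]]
        net.biases[1][...] = [-1.0]
        x = np.array([[0.25]])
        expected = 3.0 * np.tanh(2.0 * 0.25 + 0.5) - 1.0
        assert predict(net, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_feature_mismatch(self):
        arch = MLPArchitecture(neurons=(2,), transfer=("tansig",))
        net = init_mlp(arch, 3, seed=0)
        with pytest.raises(ShapeError):
            predict(net, np.zeros((2, 4)))
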