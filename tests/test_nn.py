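"""Construction, parameter counting, training and inference of the dense nets."""

import numpy as np
import pytest

from hydrosip import DenseNetModel, NetArchitecture, TrainConfig, count_weights, train

TABLE_ARCHS = [
    ((1,), 8),
    ((2,), 15),
    ((3,), 22),
    ((4,), 29),
    ((5,), 36),
    ((20,), 141),
    ((20, 15), 451),
]


class TestCountWeights:
    @pytest.mark.parametrize("hidden,expected", TABLE_ARCHS)
    def test_five_input_architectures(self, hidden, expected):
        assert count_weights(NetArchitecture(n_inputs=5, hidden_sizes=hidden)) == expected

    def test_no_hidden_layer(self):
        assert count_weights(NetArchitecture(n_inputs=5, hidden_sizes=())) == 6

    def test_matches_instantiated_parameter_arrays(self, rng):
        for _ in range(20):
            arch = NetArchitecture(
                n_inputs=int(rng.integers(1, 8)),
                hidden_sizes=tuple(rng.integers(1, 10, size=rng.integers(0, 3))),
            )
            sizes = arch.layer_sizes
            weights = [np.zeros((a, b)) for a, b in zip(sizes, sizes[1:])]
            biases = [np.zeros(b) for b in sizes[1:]]
            model = DenseNetModel(architecture=arch, weights=weights, biases=biases)
            n = sum(w.size for w in model.weights) + sum(b.size for b in model.biases)
            assert n == count_weights(arch)


def forward_oracle(model, X):
    """Independent matrix-product forward pass."""
    a = (np.asarray(X, float) - model.scaler_mean) / model.scaler_scale
    for w, b in zip(model.weights[:-1], model.biases[:-1]):
        a = np.maximum(a @ w + b, 0.0)
    z = a @ model.weights[-1] + model.biases[-1]
    return (1.0 / (1.0 + np.exp(-z)))[:, 0]


def random_model(rng, n_inputs=None):
    arch = NetArchitecture(
        n_inputs=n_inputs or int(rng.integers(1, 8)),
        hidden_sizes=tuple(rng.integers(1, 12, size=rng.integers(0, 3))),
    )
    sizes = arch.layer_sizes
    return DenseNetModel(
        architecture=arch,
        weights=[rng.normal(0, 1, (a, b)) for a, b in zip(sizes, sizes[1:])],
        biases=[rng.normal(0, 1, b) for b in sizes[1:]],
    )


class TestForwardPass:
    def test_zero_weights_give_half(self, rng):
        arch = NetArchitecture(n_inputs=5, hidden_sizes=(3,))
        sizes = arch.layer_sizes
        model = DenseNetModel(
            architecture=arch,
            weights=[np.zeros((a, b)) for a, b in zip(sizes, sizes[1:])],
            biases=[np.zeros(b) for b in sizes[1:]],
        )
        for _ in range(5):
            assert model.predict_proba(rng.normal(0, 3, 5)) == pytest.approx(0.5)

    def test_single_layer_closed_form_sigmoid(self):
        arch = NetArchitecture(n_inputs=5, hidden_sizes=())
        model = DenseNetModel(
            architecture=arch,
            weights=[np.array([[1.0], [0.0], [0.0], [0.0], [0.0]])],
            biases=[np.zeros(1)],
        )
        p = model.predict_proba([2.0, 9.9, -3.0, 1.0, 0.0])
        assert p == pytest.approx(1.0 / (1.0 + np.exp(-2.0)))

    def test_classify_respects_threshold(self):
        arch = NetArchitecture(n_inputs=1, hidden_sizes=())
        model = DenseNetModel(
            architecture=arch, weights=[np.array([[1.0]])], biases=[np.zeros(1)],
            decision_threshold=0.5,
        )
        assert model.classify([np.log(0.49 / 0.51)]) == 0  # proba 0.49
        assert model.classify([0.0]) == 1                  # proba 0.50

    def test_dimension_mismatch_rejected(self, rng):
        model = random_model(rng, n_inputs=4)
        with pytest.raises(ValueError):
            model.predict_proba([1.0, 2.0])

    def test_agrees_with_matrix_oracle(self, rng):
        for _ in range(100):
            model = random_model(rng)
            X = rng.normal(0, 2, (5, model.architecture.n_inputs))
            np.testing.assert_allclose(
                model.forward(X), forward_oracle(model, X), rtol=1e-10, atol=1e-12
            )


def separable_data(rng, n=200):
    y = rng.integers(0, 2, n)
    X = rng.normal(0, 0.5, (n, 2)) + np.where(y[:, None] == 1, 2.0, -2.0)
    return X, y


class TestTrain:
    def test_separable_data_reaches_high_validation_accuracy(self, rng):
        X, y = separable_data(rng)
        # independent separability oracle: a linear model already gets >= 0.95
        from sklearn.linear_model import LogisticRegression

        oracle = LogisticRegression().fit(X, y)
        assert oracle.score(X, y) >= 0.95
        _, history = train(
            X, y, NetArchitecture(n_inputs=2, hidden_sizes=(2,)),
            TrainConfig(seed=0, epochs=100),
        )
        assert history["val_accuracy"] >= 0.95

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (20, 2))
        with pytest.raises(ValueError):
            train(X, np.ones(20), NetArchitecture(n_inputs=2, hidden_sizes=(2,)))

    def test_nan_features_rejected(self, rng):
        X = rng.normal(0, 1, (20, 2))
        X[3, 1] = np.nan
        y = np.array([0, 1] * 10)
        with pytest.raises(ValueError):
            train(X, y, NetArchitecture(n_inputs=2, hidden_sizes=(2,)))

    def test_same_seed_bit_identical(self, rng):
        X, y = separable_data(rng, n=80)
        arch = NetArchitecture(n_inputs=2, hidden_sizes=(3,))
        cfg = TrainConfig(seed=7, epochs=30)
        m1, _ = train(X, y, arch, cfg)
        m2, _ = train(X, y, arch, cfg)
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)
        for b1, b2 in zip(m1.biases, m2.biases):
            assert np.array_equal(b1, b2)

    def test_adam_also_learns(self, rng):
        X, y = separable_data(rng)
        _, history = train(
            X, y, NetArchitecture(n_inputs=2, hidden_sizes=(3,)),
            TrainConfig(optimizer="adam", epochs=60, batch_size=10, seed=0),
        )
        assert history["val_accuracy"] >= 0.95

    def test_loss_decreases_overall(self, rng):
        X, y = separable_data(rng)
        _, history = train(
            X, y, NetArchitecture(n_inputs=2, hidden_sizes=(2,)),
            TrainConfig(seed=1, epochs=50),
        )
        assert history["train_loss"][-1] < history["train_loss"][0]
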