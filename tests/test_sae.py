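"""Sparse autoencoder core: costs, exact gradients, greedy stacking,
softmax head and end-to-end fine-tuning."""

import numpy as np
import pytest
from scipy.special import expit

from conftest import central_difference_gradient, gradient_relative_error
from p300sae.sae import (
    AutoencoderLayer,
    FeatureScaler,
    SAEHyperparams,
    StackedNetwork,
    ae_cost_and_gradient,
    encode,
    fine_tune,
    initialize_network,
    network_cost_and_gradient,
    load_model,
    predict,
    save_model,
    softmax_cost_and_gradient,
    train_autoencoder,
    train_sae,
    train_softmax,
    train_stack,
)
from p300sae.io import split_validation
from p300sae.features import FeatureMatrix


def _random_layer(d, h, rng, scale=0.5):
    return AutoencoderLayer(
        encode_weights=scale * rng.normal(size=(h, d)),
        encode_bias=scale * rng.normal(size=h),
        decode_weights=scale * rng.normal(size=(d, h)),
        decode_bias=scale * rng.normal(size=d),
    )


class TestAutoencoderCost:
    def test_cost_vanishes_at_perfect_sparse_reconstruction(self):
        """With lambda = 0, perfect reconstruction and every mean hidden
        activation equal to rho, all three terms vanish."""
        hyper = SAEHyperparams(l2_weight=0.0, sparsity_weight=4.0, sparsity_target=0.5)
        # zero weights/biases: H = 0.5 everywhere = rho; feed X = 0.5 so
        # the decoder output sigmoid(0) = 0.5 reconstructs exactly
        layer = AutoencoderLayer(np.zeros((3, 4)), np.zeros(3), np.zeros((4, 3)), np.zeros(4))
        X = np.full((5, 4), 0.5)
        cost, _ = ae_cost_and_gradient(layer, X, hyper)
        assert cost == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_mse_without_regularization(self, rng):
        hyper = SAEHyperparams(l2_weight=0.0, sparsity_weight=0.0)
        layer = _random_layer(6, 3, rng)
        X = rng.uniform(0.1, 0.9, size=(8, 6))
        H = expit(X @ layer.encode_weights.T + layer.encode_bias)
        Xhat = expit(H @ layer.decode_weights.T + layer.decode_bias)
        cost, _ = ae_cost_and_gradient(layer, X, hyper)
        assert cost == pytest.approx(np.mean((Xhat - X) ** 2))

    def test_sparsity_penalty_positive_away_from_target(self, rng):
        base = SAEHyperparams(l2_weight=0.0, sparsity_weight=0.0)
        sparse = SAEHyperparams(l2_weight=0.0, sparsity_weight=4.0, sparsity_target=0.2)
        layer = _random_layer(6, 3, rng)
        X = rng.uniform(0.1, 0.9, size=(8, 6))
        plain, _ = ae_cost_and_gradient(layer, X, base)
        with_kl, _ = ae_cost_and_gradient(layer, X, sparse)
        assert with_kl > plain

    def test_analytic_gradient_matches_central_differences(self, rng):
        """Core oracle: every AE parameter gradient agrees with central
        finite differences to <= 1e-6 relative error on a toy layer."""
        hyper = SAEHyperparams(l2_weight=0.004, sparsity_weight=4.0, sparsity_target=0.2)
        layer = _random_layer(6, 3, rng)
        X = rng.uniform(0.1, 0.9, size=(7, 6))
        _, grads = ae_cost_and_gradient(layer, X, hyper)

        shapes = {k: getattr(layer, k).shape for k in grads}

        def unpack(vec):
            out, i = {}, 0
            for k, s in shapes.items():
                size = int(np.prod(s))
                out[k] = vec[i : i + size].reshape(s)
                i += size
            return AutoencoderLayer(**out)

        x0 = np.concatenate([getattr(layer, k).ravel() for k in shapes])
        f = lambda v: ae_cost_and_gradient(unpack(v), X, hyper)[0]
        numeric = central_difference_gradient(f, x0)
        analytic = np.concatenate([grads[k].ravel() for k in shapes])
        assert gradient_relative_error(analytic, numeric) <= 1e-6

    def test_saturated_activations_are_clamped(self, caplog):
        layer = AutoencoderLayer(
            np.full((2, 3), 50.0), np.zeros(2), np.zeros((3, 2)), np.zeros(3)
        )
        X = np.ones((4, 3))
        with caplog.at_level("WARNING"):
            cost, _ = ae_cost_and_gradient(layer, X, SAEHyperparams())
        assert np.isfinite(cost)

    def test_shape_mismatch_rejected(self, rng):
        layer = _random_layer(6, 3, rng)
        with pytest.raises(ValueError):
            ae_cost_and_gradient(layer, np.ones((4, 5)), SAEHyperparams())


class TestEncode:
    def test_zero_parameters_give_half(self):
        layer = AutoencoderLayer(np.zeros((3, 4)), np.zeros(3), np.zeros((4, 3)), np.zeros(4))
        assert np.allclose(encode(layer, np.random.default_rng(0).normal(size=(5, 4))), 0.5)

    def test_output_strictly_inside_unit_interval(self, rng):
        layer = _random_layer(4, 2, rng, scale=3.0)
        H = encode(layer, rng.normal(size=(10, 4)))
        assert np.all((H > 0) & (H < 1))

    def test_matches_hand_computed_two_by_two(self):
        layer = AutoencoderLayer(
            np.array([[1.0, -1.0], [0.5, 0.5]]), np.array([0.0, 1.0]),
            np.zeros((2, 2)), np.zeros(2),
        )
        X = np.array([[2.0, 1.0]])
        expected = expit(np.array([2.0 - 1.0, 0.5 * 2 + 0.5 * 1 + 1.0]))
        assert np.allclose(encode(layer, X)[0], expected)


class TestTrainAutoencoder:
    def test_low_rank_data_reconstructed_by_matching_bottleneck(self, rng):
        # 2 latent factors embedded in 10 dims; an AE with 2 hidden units
        # should capture most of the variance (linear rank-2 is the bound)
        Z = rng.normal(size=(120, 2))
        A = rng.normal(size=(2, 10))
        X = Z @ A
        X = FeatureScaler.fit(X).transform(X)
        hyper = SAEHyperparams(
            l2_weight=0.0, sparsity_weight=0.0, max_pretrain_epochs=800, learning_rate=1.0
        )
        layer = train_autoencoder(X, 2, hyper, rng=np.random.default_rng(0))
        H = encode(layer, X)
        Xhat = expit(H @ layer.decode_weights.T + layer.decode_bias)
        mse = np.mean((Xhat - X) ** 2)
        assert mse < 0.2 * X.var()

    def test_zero_epochs_returns_initialization(self, rng):
        X = rng.uniform(0.1, 0.9, size=(10, 6))
        hyper = SAEHyperparams(max_pretrain_epochs=0)
        a = train_autoencoder(X, 3, hyper, rng=np.random.default_rng(5))
        b = train_autoencoder(X, 3, hyper, rng=np.random.default_rng(5))
        assert np.array_equal(a.encode_weights, b.encode_weights)
        assert not a.encode_bias.any()  # untouched init

    def test_training_never_increases_cost(self, rng):
        X = rng.uniform(0.1, 0.9, size=(20, 8))
        hyper = SAEHyperparams(max_pretrain_epochs=50)
        init = train_autoencoder(X, 4, SAEHyperparams(max_pretrain_epochs=0), np.random.default_rng(3))
        trained = train_autoencoder(X, 4, hyper, np.random.default_rng(3))
        c0, _ = ae_cost_and_gradient(init, X, hyper)
        c1, _ = ae_cost_and_gradient(trained, X, hyper)
        assert c1 <= c0

    def test_same_seed_identical_parameters(self, rng):
        X = rng.uniform(0.1, 0.9, size=(15, 6))
        hyper = SAEHyperparams(max_pretrain_epochs=20)
        a = train_autoencoder(X, 3, hyper, np.random.default_rng(9))
        b = train_autoencoder(X, 3, hyper, np.random.default_rng(9))
        assert np.array_equal(a.encode_weights, b.encode_weights)
        assert np.array_equal(a.decode_bias, b.decode_bias)

    def test_hidden_size_must_compress(self, rng):
        with pytest.raises(ValueError):
            train_autoencoder(rng.uniform(size=(10, 4)), 4, SAEHyperparams(), rng)


class TestTrainStack:
    def test_greedy_stack_produces_requested_code_sizes(self, rng):
        X = rng.uniform(0.1, 0.9, size=(30, 20))
        hyper = SAEHyperparams(layer_sizes=(8, 4), max_pretrain_epochs=10)
        layers = train_stack(X, hyper, np.random.default_rng(1))
        H = X
        sizes = []
        for layer in layers:
            H = encode(layer, H)
            sizes.append(H.shape[1])
        assert sizes == [8, 4]

    def test_single_layer_stack_equals_one_autoencoder(self, rng):
        X = rng.uniform(0.1, 0.9, size=(20, 10))
        hyper = SAEHyperparams(layer_sizes=(4,), max_pretrain_epochs=15)
        master = np.random.default_rng(2)
        layers = train_stack(X, hyper, master)
        solo = train_autoencoder(X, 4, hyper, np.random.default_rng(2).spawn(1)[0])
        assert np.array_equal(layers[0].encode_weights, solo.encode_weights)

    def test_each_layer_trained_on_previous_encoding(self, rng):
        X = rng.uniform(0.1, 0.9, size=(25, 16))
        hyper = SAEHyperparams(layer_sizes=(8, 4), max_pretrain_epochs=5)
        seen = {}
        train_stack(X, hyper, np.random.default_rng(3), layer_callback=lambda k, H: seen.update({k: H.copy()}))
        assert np.array_equal(seen[0], X)
        assert seen[1].shape == (25, 8)
        assert np.all((seen[1] > 0) & (seen[1] < 1))

    def test_non_decreasing_sizes_rejected(self, rng):
        X = rng.uniform(size=(10, 8))
        with pytest.raises(ValueError):
            train_stack(X, SAEHyperparams(layer_sizes=(4, 6)), rng)


class TestSoftmax:
    def test_separable_toy_problem_fit_perfectly(self, rng):
        H = np.vstack([rng.normal(-2, 0.3, size=(30, 2)), rng.normal(2, 0.3, size=(30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        W, b = train_softmax(H, y, iterations=200)
        Z = H @ W.T + b
        assert np.mean(np.argmax(Z, axis=1) == y) == 1.0

    def test_probabilities_row_normalized(self, rng):
        from p300sae.sae import softmax_probabilities

        P = softmax_probabilities(rng.normal(size=(40, 3)), rng.normal(size=(2, 3)), rng.normal(size=2))
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_gradient_matches_central_differences(self, rng):
        H = rng.normal(size=(9, 4))
        y = rng.integers(0, 2, size=9)
        y[0], y[1] = 0, 1
        W, b = rng.normal(size=(2, 4)), rng.normal(size=2)
        _, gW, gb = softmax_cost_and_gradient(W, b, H, y)

        def f(vec):
            Wv, bv = vec[:8].reshape(2, 4), vec[8:]
            return softmax_cost_and_gradient(Wv, bv, H, y)[0]

        numeric = central_difference_gradient(f, np.concatenate([W.ravel(), b]))
        analytic = np.concatenate([gW.ravel(), gb])
        assert gradient_relative_error(analytic, numeric) <= 1e-6

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_softmax(rng.normal(size=(5, 2)), np.zeros(5, dtype=int))


class TestFineTuneAndPredict:
    def _toy_network(self, rng, sizes=(4, 3)):
        return initialize_network(5, sizes, 2, rng)

    def test_zero_iterations_is_identity(self, rng):
        net = self._toy_network(np.random.default_rng(0))
        X = rng.normal(size=(10, 5))
        y = rng.integers(0, 2, size=10)
        out = fine_tune(net, X, y, SAEHyperparams(layer_sizes=(4, 3), finetune_iterations=0))
        assert np.array_equal(out.layers[0].encode_weights, net.layers[0].encode_weights)
        assert np.array_equal(out.softmax_weights, net.softmax_weights)

    def test_full_network_gradient_matches_central_differences(self, rng):
        """End-to-end backpropagation through a 5-4-3-2 network passes the
        finite-difference check."""
        net = initialize_network(5, (4, 3), 2, np.random.default_rng(7))
        X = rng.uniform(0.1, 0.9, size=(8, 5))
        y = rng.integers(0, 2, size=8)
        y[0], y[1] = 0, 1
        _, grads = network_cost_and_gradient(net, X, y)
        from p300sae.sae import _flatten, _network_params, _set_network_params, _unflatten

        x0, shapes = _flatten(_network_params(net))

        def f(vec):
            _set_network_params(net, _unflatten(vec, shapes))
            return network_cost_and_gradient(net, X, y)[0]

        numeric = central_difference_gradient(f, x0.copy())
        _set_network_params(net, _unflatten(x0, shapes))
        analytic, _ = _flatten(grads)
        assert gradient_relative_error(analytic, numeric) <= 1e-6

    def test_fine_tuning_does_not_hurt_validation_on_clean_data(self, rng):
        """On well-separated synthetic features, validation accuracy after
        fine-tuning is at least the pre-fine-tuning accuracy."""
        n = 150
        X = np.vstack([rng.normal(-1, 0.4, size=(n, 6)), rng.normal(1, 0.4, size=(n, 6))])
        y = np.array([0] * n + [1] * n)
        perm = np.random.default_rng(0).permutation(2 * n)
        X, y = X[perm], y[perm]
        fm = FeatureMatrix(X, y)
        tr, va = split_validation(fm, 0.2, np.random.default_rng(1))
        hyper = SAEHyperparams(
            layer_sizes=(4,), max_pretrain_epochs=50, softmax_iterations=100, finetune_iterations=100
        )
        scaler = FeatureScaler.fit(tr.values)
        layers = train_stack(scaler.transform(tr.values), hyper, np.random.default_rng(2))
        H = encode(layers[0], scaler.transform(tr.values))
        W, b = train_softmax(H, tr.labels, 100)
        net = StackedNetwork(layers, W, b, scaler)
        before = np.mean(predict(net, va.values)[0] == va.labels)
        tuned = fine_tune(net, tr.values, tr.labels, hyper, X_val=va.values, labels_val=va.labels)
        after = np.mean(predict(tuned, va.values)[0] == va.labels)
        assert after >= before

    def test_predict_argmax_and_tie_break(self):
        net = StackedNetwork(layers=[], softmax_weights=np.zeros((2, 3)), softmax_bias=np.array([0.0, 0.0]))
        labels, P = predict(net, np.ones((4, 3)))
        assert np.allclose(P, 0.5)
        assert np.array_equal(labels, np.zeros(4))  # exact tie -> lower class index

    def test_prediction_invariant_under_row_permutation(self, rng):
        net = initialize_network(5, (3,), 2, np.random.default_rng(4))
        X = rng.normal(size=(12, 5))
        perm = rng.permutation(12)
        labels, _ = predict(net, X)
        labels_p, _ = predict(net, X[perm])
        assert np.array_equal(labels[perm], labels_p)

    def test_dimension_mismatch_rejected(self, rng):
        net = initialize_network(5, (3,), 2, rng)
        with pytest.raises(ValueError):
            predict(net, np.ones((2, 4)))


class TestArchitectureAndSerialization:
    def test_default_architecture_string(self):
        net = initialize_network(209, (130, 100, 50, 20), 2, np.random.default_rng(0))
        assert net.architecture == "209-130-100-50-20-2"

    def test_model_round_trip(self, tmp_path, rng):
        net = initialize_network(6, (4, 3), 2, np.random.default_rng(1),
                                 scaler=FeatureScaler.fit(rng.normal(size=(10, 6))))
        save_model(net, tmp_path / "m.h5")
        back = load_model(tmp_path / "m.h5")
        X = rng.normal(size=(5, 6))
        assert np.array_equal(predict(net, X)[0], predict(back, X)[0])
        assert back.architecture == net.architecture

    def test_train_sae_end_to_end_deterministic(self, rng):
        X = rng.normal(size=(60, 10))
        y = rng.integers(0, 2, size=60)
        y[:2] = [0, 1]
        hyper = SAEHyperparams(
            layer_sizes=(6, 3), max_pretrain_epochs=10, softmax_iterations=20, finetune_iterations=10
        )
        a = train_sae(X, y, hyper, rng=np.random.default_rng(11))
        b = train_sae(X, y, hyper, rng=np.random.default_rng(11))
        assert np.array_equal(a.softmax_weights, b.softmax_weights)
        assert np.array_equal(a.layers[0].encode_weights, b.layers[0].encode_weights)
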