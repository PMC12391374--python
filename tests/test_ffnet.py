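import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from chirpff.features import FeatureMatrix
from chirpff.ffnet import (
    FFLayer,
    FFNetwork,
    TrainConfig,
    _loss_and_grads,
    goodness,
    layer_loss,
    layer_normalize,
    load_checkpoint,
    save_checkpoint,
    sigmoid,
    train_layer,
    train_network,
)


class TestGoodness:
    def test_rms_on_three_four(self):
        res = goodness([3.0, 4.0], "rms", theta=3.5)
        assert res.g == pytest.approx(np.sqrt(12.5), abs=1e-9)
        assert res.p == pytest.approx(sigmoid(np.sqrt(12.5) - 3.5), abs=1e-9)

    def test_sum_of_squares_on_three_four(self):
        assert goodness([3.0, 4.0], "sum_sq").g == pytest.approx(25.0)

    def test_zero_vector_squashes_to_sigmoid_of_minus_theta(self):
        res = goodness(np.zeros(7), "rms", theta=3.5)
        assert res.g == 0.0
        assert res.p == pytest.approx(1 / (1 + np.exp(3.5)), abs=1e-9)

    def test_goodness_at_threshold_gives_half(self):
        assert goodness([3.5], "mean_abs", theta=3.5).p == pytest.approx(0.5)

    def test_rms_equals_scaled_sum_of_squares(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            v = rng.uniform(0, 2, size=rng.integers(1, 30))
            r = goodness(v, "rms").g
            s = goodness(v, "sum_sq").g
            assert abs(r - np.sqrt(s / v.size)) < 1e-10

    def test_squash_strictly_increasing_in_goodness(self):
        g = np.linspace(0, 10, 50)
        p = sigmoid(g - 3.5)
        assert np.all(np.diff(p) > 0)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            goodness([], "rms")


class TestLayerLoss:
    def test_both_batches_at_threshold(self):
        loss = layer_loss([3.5], [3.5], theta=3.5)
        assert loss.l_pos == pytest.approx(np.log(2), abs=1e-12)
        assert loss.l_neg == pytest.approx(np.log(2), abs=1e-12)
        assert loss.total == pytest.approx((2 * np.log(2)) ** 2, abs=1e-9)

    def test_vanishes_when_batches_are_well_separated(self):
        assert layer_loss([1e4], [-1e4], theta=0.0).total == pytest.approx(0.0, abs=1e-12)

    def test_stable_for_huge_arguments(self):
        loss = layer_loss([-1e4], [1e4], theta=0.0)
        assert np.isfinite(loss.total)

    def test_sign_symmetry_at_zero_threshold(self):
        g_a, g_b = [0.3, 1.2], [-0.7, 0.1]
        forward = layer_loss(g_a, g_b, theta=0.0).total
        swapped = layer_loss([-g for g in g_b], [-g for g in g_a], theta=0.0).total
        assert forward == pytest.approx(swapped, rel=1e-12)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            layer_loss([], [1.0])


class TestLayerNormalize:
    def test_three_four_five_triangle(self):
        assert np.allclose(layer_normalize([3.0, 4.0]), [0.6, 0.8])

    def test_zero_vector_passes_through(self):
        assert np.allclose(layer_normalize(np.zeros(5)), 0.0)

    def test_output_has_unit_norm(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(100, 17))
        norms = np.linalg.norm(layer_normalize(v), axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)


_activity_vectors = arrays(
    np.float64,
    st.integers(1, 40),
    elements=st.floats(0.0, 100.0, allow_nan=False),
)


class TestGoodnessProperties:
    @settings(derandomize=True, max_examples=50)
    @given(_activity_vectors)
    def test_rms_is_root_of_mean_square(self, v):
        assert goodness(v, "rms").g == pytest.approx(
            np.sqrt(goodness(v, "sum_sq").g / v.size), abs=1e-10
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        arrays(np.float64, st.integers(1, 40),
               elements=st.floats(0.0, 10.0, allow_nan=False)),
        st.floats(-5, 5),
    )
    def test_squashed_score_lies_strictly_inside_unit_interval(self, v, theta):
        # strict in exact arithmetic; the bounded range keeps float64 from
        # saturating the sigmoid
        p = goodness(v, "mean_abs", theta=theta).p
        assert 0.0 < p < 1.0

    @settings(derandomize=True, max_examples=50)
    @given(arrays(np.float64, st.integers(1, 30),
                  elements=st.floats(-50, 50, allow_nan=False)))
    def test_normalized_vector_never_exceeds_unit_norm(self, v):
        norm = np.linalg.norm(layer_normalize(v))
        assert norm <= 1.0 + 1e-9
        if np.linalg.norm(v) > 1e-6:
            assert norm == pytest.approx(1.0, abs=1e-9)


def _toy_batches(rng, n=8):
    """Positives along +x, negatives along +y, linearly separable."""
    pos = np.column_stack([rng.uniform(2, 4, n), rng.uniform(0, 0.2, n)])
    neg = np.column_stack([rng.uniform(0, 0.2, n), rng.uniform(2, 4, n)])
    return pos, neg


class TestGradients:
    def test_analytic_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(42)
        layer = FFLayer(5, 3, rng, goodness_kind="rms", theta=3.5)
        x_pos = rng.uniform(0, 1, size=(4, 5))
        x_neg = rng.uniform(0, 1, size=(4, 5))

        def total_loss():
            g_p = layer.goodness(x_pos).g
            g_n = layer.goodness(x_neg).g
            return layer_loss(g_p, g_n, 3.5).total

        _, d_w, d_b = _loss_and_grads(layer, x_pos, x_neg, 3.5)
        h = 1e-6
        num_w = np.zeros_like(layer.weights)
        for i in range(layer.n_out):
            for j in range(layer.n_in):
                layer.weights[i, j] += h
                up = total_loss()
                layer.weights[i, j] -= 2 * h
                down = total_loss()
                layer.weights[i, j] += h
                num_w[i, j] = (up - down) / (2 * h)
        assert np.linalg.norm(d_w - num_w) < 1e-4 * max(np.linalg.norm(num_w), 1e-12)
        num_b = np.zeros_like(layer.bias)
        for i in range(layer.n_out):
            layer.bias[i] += h
            up = total_loss()
            layer.bias[i] -= 2 * h
            down = total_loss()
            layer.bias[i] += h
            num_b[i] = (up - down) / (2 * h)
        assert np.linalg.norm(d_b - num_b) < 1e-4 * max(np.linalg.norm(num_b), 1e-12)

    def test_subspace_shortcut_matches_direct_descent(self):
        # n_in >> n_samples triggers the span projection; the trajectory
        # must match an explicit direct-space descent
        rng = np.random.default_rng(7)
        n_in = 60
        x_pos = rng.uniform(0, 1, size=(5, n_in))
        x_neg = rng.uniform(0, 1, size=(5, n_in))
        config = TrainConfig(epochs=50, batch_size=None, learning_rate=0.05)
        layer_a = FFLayer(n_in, 4, np.random.default_rng(1))
        layer_b = FFLayer(n_in, 4, np.random.default_rng(1))
        train_layer(layer_a, x_pos, x_neg, config)  # projected internally
        for _ in range(config.epochs):  # direct reference loop
            _, d_w, d_b = _loss_and_grads(layer_b, x_pos, x_neg, config.theta)
            layer_b.weights -= config.learning_rate * d_w
            layer_b.bias -= config.learning_rate * d_b
        assert np.allclose(layer_a.weights, layer_b.weights, atol=1e-8)
        assert np.allclose(layer_a.bias, layer_b.bias, atol=1e-8)


class TestTrainLayer:
    def test_separates_linearly_separable_toy_set(self):
        rng = np.random.default_rng(0)
        pos, neg = _toy_batches(rng, n=16)
        layer = FFLayer(2, 4, rng)
        config = TrainConfig(epochs=200)
        train_layer(layer, pos, neg, config, rng=np.random.default_rng(1))
        g_pos = layer.goodness(pos).g.mean()
        g_neg = layer.goodness(neg).g.mean()
        assert g_pos > config.theta > g_neg

    def test_zero_learning_rate_leaves_weights_unchanged(self):
        rng = np.random.default_rng(0)
        pos, neg = _toy_batches(rng)
        layer = FFLayer(2, 4, rng)
        before = layer.weights.copy()
        train_layer(layer, pos, neg, TrainConfig(learning_rate=0.0, epochs=20))
        assert np.array_equal(layer.weights, before)

    def test_full_batch_loss_history_non_increasing_at_small_step(self):
        rng = np.random.default_rng(2)
        pos, neg = _toy_batches(rng, n=16)
        layer = FFLayer(2, 4, rng)
        history = train_layer(
            layer, pos, neg,
            TrainConfig(learning_rate=1e-3, epochs=200, batch_size=None),
        )
        assert len(history) == 200
        assert np.all(np.diff(history) <= 1e-12)


def _tiny_config(**kw):
    defaults = dict(epochs=30, layer_sizes=(8, 8), seed=99)
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestTrainNetwork:
    def test_same_seed_gives_bit_identical_weights(self, toy_features):
        a = train_network(toy_features, _tiny_config())
        b = train_network(toy_features, _tiny_config())
        for la, lb in zip(a.layers, b.layers):
            assert np.array_equal(la.weights, lb.weights)
            assert np.array_equal(la.bias, lb.bias)

    def test_predict_before_training_raises(self, toy_features):
        net = FFNetwork(toy_features[0].values.size, _tiny_config())
        with pytest.raises(RuntimeError):
            net.predict(toy_features[0])

    def test_loss_history_recorded_per_layer(self, toy_features):
        net = train_network(toy_features, _tiny_config())
        assert len(net.loss_histories) == 2
        assert all(len(h) == 30 for h in net.loss_histories)

    def test_prediction_ignores_stored_label(self, toy_features):
        net = train_network(toy_features, _tiny_config())
        m = toy_features[0]
        relabelled = FeatureMatrix(m.values, source_id=m.source_id, label=1 - m.label)
        assert net.predict(m)[0] == net.predict(relabelled)[0]

    def test_checkpoint_round_trip(self, toy_features, tmp_path):
        net = train_network(toy_features, _tiny_config())
        path = tmp_path / "model.npz"
        save_checkpoint(net, path)
        back = load_checkpoint(path)
        for la, lb in zip(net.layers, back.layers):
            assert np.array_equal(la.weights, lb.weights)
        pred_a, margin_a = net.predict_batch(toy_features)
        pred_b, margin_b = back.predict_batch(toy_features)
        assert np.array_equal(pred_a, pred_b)
        assert np.allclose(margin_a, margin_b)


class TestPredict:
    @staticmethod
    def _hand_built(second_layer_diag):
        cfg = TrainConfig(layer_sizes=(2, 2), calibrate_init=False)
        net = FFNetwork(13, cfg)  # one 13-coefficient frame, no scaler
        w1 = np.zeros((2, 13))
        w1[0, 0:5] = 1.0  # unit 0 fires on the label-0 code block
        w1[1, 5:10] = 1.0  # unit 1 fires on the label-1 code block
        net.layers[0].weights = w1
        net.layers[0].bias = np.zeros(2)
        net.layers[1].weights = np.diag(second_layer_diag).astype(float)
        net.layers[1].bias = np.zeros(2)
        net.trained = True
        return net

    def test_label_with_higher_accumulated_goodness_wins(self):
        # label-0 encoding yields second-layer activities [2, 0] (rms sqrt(2));
        # label-1 yields [0, 1] (rms sqrt(0.5)) -> label 0 wins
        net = self._hand_built([2.0, 1.0])
        features = FeatureMatrix(np.zeros((1, 13)), "hand")
        label, accum, margin = net.predict(features)
        assert label == 0
        assert accum[0] == pytest.approx(np.sqrt(2.0))
        assert accum[1] == pytest.approx(np.sqrt(0.5))
        assert margin == pytest.approx(accum[1] - accum[0])

    def test_exact_tie_breaks_toward_label_zero(self):
        net = self._hand_built([1.0, 1.0])
        label, accum, margin = net.predict(FeatureMatrix(np.zeros((1, 13)), "h"))
        assert accum[0] == accum[1]
        assert label == 0


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-0.1)
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(goodness_kind="max")
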