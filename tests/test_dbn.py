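import numpy as np
import pytest

from dbnsurv.dbn import (
    DBNModel,
    FineTuneConfig,
    FineTunedNet,
    cross_entropy,
    fine_tune,
    init_classifier_from_dbn,
    init_classifier_random,
    loss_and_gradients,
    pretrain_dbn,
    softmax,
)
from dbnsurv.rbm import RBMParams, TrainConfig, hidden_conditional


def _two_blob_data(rng, n=80, d=6):
    y = rng.integers(0, 2, n)
    X = rng.normal(0, 0.3, (n, d)) + np.where(y[:, None] == 1, 0.8, 0.2)
    return X, y


def _random_net(rng, d=4, sizes=(5, 3)):
    return init_classifier_random(d, list(sizes), head_width=4, seed=int(rng.integers(1 << 30)))


class TestPretrainDBN:
    def test_layer_shapes_chain(self, rng):
        data = (rng.random((40, 7)) < 0.5).astype(float)
        dbn = pretrain_dbn(data, [5, 3], TrainConfig(epochs=5, seed=0))
        assert [(l.n_visible, l.n_hidden) for l in dbn.layers] == [(7, 5), (5, 3)]

    def test_transform_shape_and_range(self, rng):
        data = (rng.random((30, 6)) < 0.5).astype(float)
        dbn = pretrain_dbn(data, [4, 2], TrainConfig(epochs=3, seed=1))
        out = dbn.transform(data)
        assert out.shape == (30, 2)
        assert ((out > 0) & (out < 1)).all()

    def test_second_layer_trained_on_first_layer_means(self, rng):
        # with 0 epochs for layer 2 this is untestable, so instead check that
        # training the second layer manually on the first layer's means
        # reproduces the stacked result exactly
        data = (rng.random((30, 6)) < 0.5).astype(float)
        cfg = TrainConfig(epochs=10, seed=5)
        dbn = pretrain_dbn(data, [4, 3], cfg)
        from dbnsurv.rbm import train_rbm

        first = dbn.layers[0]
        means = hidden_conditional(first, data)
        second = train_rbm(
            means,
            3,
            TrainConfig(
                k=cfg.k,
                learning_rate=cfg.learning_rate,
                batch_size=cfg.batch_size,
                weight_decay=cfg.weight_decay,
                epochs=cfg.epochs,
                seed=cfg.seed + 1,
            ),
        )
        np.testing.assert_array_equal(dbn.layers[1].W, second.W)

    def test_mismatched_layer_dims_rejected(self):
        a = RBMParams(np.zeros((4, 3)), np.zeros(4), np.zeros(3))
        b = RBMParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2))
        with pytest.raises(ValueError):
            DBNModel([a, b])

    def test_empty_data_raises(self):
        with pytest.raises(ValueError):
            pretrain_dbn(np.empty((0, 4)), [2], TrainConfig(epochs=1))


class TestClassifierInit:
    def test_dbn_weights_copied_verbatim(self, rng):
        data = (rng.random((20, 5)) < 0.5).astype(float)
        dbn = pretrain_dbn(data, [4, 3], TrainConfig(epochs=2, seed=0))
        net = init_classifier_from_dbn(dbn, head_width=6, seed=1)
        for layer, (W, b) in zip(dbn.layers, net.hidden):
            np.testing.assert_array_equal(W, layer.W)
            np.testing.assert_array_equal(b, layer.c)
        assert net.hidden[-1][0].shape == (3, 6)
        assert net.softmax_W.shape == (6, 2)

    def test_copied_weights_are_independent(self, rng):
        data = (rng.random((20, 5)) < 0.5).astype(float)
        dbn = pretrain_dbn(data, [3], TrainConfig(epochs=2, seed=0))
        net = init_classifier_from_dbn(dbn, seed=1)
        net.hidden[0][0][0, 0] += 99.0
        assert dbn.layers[0].W[0, 0] != net.hidden[0][0][0, 0]

    def test_random_init_shapes_match_dbn_init(self, rng):
        data = (rng.random((20, 5)) < 0.5).astype(float)
        dbn = pretrain_dbn(data, [4, 3], TrainConfig(epochs=1, seed=0))
        a = init_classifier_from_dbn(dbn, head_width=6, seed=2)
        b = init_classifier_random(5, [4, 3], head_width=6, seed=2)
        assert [W.shape for W, _ in a.hidden] == [W.shape for W, _ in b.hidden]
        assert a.softmax_W.shape == b.softmax_W.shape

    def test_zeroed_head_predicts_half(self, rng):
        net = _random_net(rng)
        net.softmax_W[:] = 0.0
        net.softmax_b[:] = 0.0
        proba = net.predict_proba(rng.normal(size=(7, 4)))
        np.testing.assert_allclose(proba, 0.5)


class TestPredictProba:
    def test_rows_sum_to_one_and_positive(self, rng):
        net = _random_net(rng)
        proba = net.predict_proba(rng.normal(size=(11, 4)))
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        assert (proba > 0).all()

    def test_softmax_overflow_safe(self):
        p = softmax(np.array([[1000.0, 0.0]]))
        np.testing.assert_allclose(p, [[1.0, 0.0]], atol=1e-12)

    def test_wrong_feature_count_raises(self, rng):
        net = _random_net(rng)
        with pytest.raises(ValueError):
            net.predict_proba(np.zeros((3, 9)))


class TestGradients:
    def test_matches_finite_differences(self, rng):
        net = _random_net(rng)
        X = rng.normal(size=(9, 4))
        y = rng.integers(0, 2, 9)
        loss, g_hidden, g_sW, g_sb = loss_and_gradients(net, X, y)
        eps = 1e-6

        def numeric(arr):
            g = np.zeros_like(arr)
            flat = arr.ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp = cross_entropy(net.predict_proba(X), y)
                flat[i] = orig - eps
                lm = cross_entropy(net.predict_proba(X), y)
                flat[i] = orig
                g.ravel()[i] = (lp - lm) / (2 * eps)
            return g

        np.testing.assert_allclose(g_sW, numeric(net.softmax_W), atol=1e-5)
        np.testing.assert_allclose(g_sb, numeric(net.softmax_b), atol=1e-5)
        for (W, b), (gW, gb) in zip(net.hidden, g_hidden):
            np.testing.assert_allclose(gW, numeric(W), atol=1e-5)
            np.testing.assert_allclose(gb, numeric(b), atol=1e-5)

    def test_loss_is_mean_negative_log_probability(self, rng):
        net = _random_net(rng)
        X = rng.normal(size=(5, 4))
        y = rng.integers(0, 2, 5)
        loss, *_ = loss_and_gradients(net, X, y)
        proba = net.predict_proba(X)
        assert loss == pytest.approx(
            -np.mean(np.log(proba[np.arange(5), y] + 1e-12))
        )


class TestFineTune:
    def test_learns_linearly_separable_blobs(self, rng):
        X, y = _two_blob_data(rng, n=120)
        net = init_classifier_random(6, [5], head_width=4, seed=0)
        out = fine_tune(
            net, (X[:90], y[:90]), (X[90:], y[90:]),
            FineTuneConfig(max_epochs=200, patience=30, seed=0),
        )
        assert np.mean(out.predict(X) == y) >= 0.9

    def test_never_worse_than_initialization_on_validation(self, rng):
        # adversarial: validation labels flipped so training can only hurt
        X, y = _two_blob_data(rng, n=60)
        Xv, yv = X[40:], 1 - y[40:]
        net = _random_net(rng, d=6, sizes=(4,))
        out = fine_tune(
            net, (X[:40], y[:40]), (Xv, yv),
            FineTuneConfig(max_epochs=50, patience=5, seed=0),
        )
        init_val = cross_entropy(net.predict_proba(Xv), yv)
        final_val = cross_entropy(out.predict_proba(Xv), yv)
        assert final_val <= init_val + 1e-12

    def test_patience_zero_stops_after_first_non_improvement(self, rng):
        X, y = _two_blob_data(rng, n=40)
        net = _random_net(rng, d=6, sizes=(4,))
        out = fine_tune(
            net, (X, y), (X, y), FineTuneConfig(max_epochs=200, patience=0, seed=0)
        )
        losses = out.history["val_loss"]
        # ran until the first epoch whose validation loss failed to improve
        assert all(b < a for a, b in zip(losses[:-2], losses[1:-1]))

    def test_does_not_mutate_input_network(self, rng):
        X, y = _two_blob_data(rng, n=40)
        net = _random_net(rng, d=6, sizes=(4,))
        W0 = net.hidden[0][0].copy()
        fine_tune(net, (X, y), (X, y), FineTuneConfig(max_epochs=3, seed=0))
        np.testing.assert_array_equal(net.hidden[0][0], W0)

    def test_deterministic_given_seed(self, rng):
        X, y = _two_blob_data(rng, n=50)
        net = _random_net(rng, d=6, sizes=(4,))
        cfg = FineTuneConfig(max_epochs=20, seed=3)
        a = fine_tune(net, (X[:35], y[:35]), (X[35:], y[35:]), cfg)
        b = fine_tune(net, (X[:35], y[:35]), (X[35:], y[35:]), cfg)
        for (Wa, ba), (Wb, bb) in zip(a.hidden, b.hidden):
            np.testing.assert_array_equal(Wa, Wb)
        np.testing.assert_array_equal(a.softmax_W, b.softmax_W)

    def test_single_class_training_labels_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        net = _random_net(rng)
        with pytest.raises(ValueError):
            fine_tune(net, (X, np.zeros(10, int)), (X, np.zeros(10, int)))

    def test_empty_validation_rejected(self, rng):
        X, y = _two_blob_data(rng, n=20, d=4)
        net = _random_net(rng)
        with pytest.raises(ValueError):
            fine_tune(net, (X, y), (np.empty((0, 4)), np.empty(0, int)))

    def test_history_bookkeeping(self, rng):
        X, y = _two_blob_data(rng, n=40)
        net = _random_net(rng, d=6, sizes=(4,))
        out = fine_tune(net, (X, y), (X, y), FineTuneConfig(max_epochs=10, patience=100, seed=0))
        h = out.history
        assert h["epochs_run"] == 10
        assert len(h["train_loss"]) == 10
        assert len(h["val_loss"]) == 11  # includes the pre-training loss
        assert h["best_val_loss"] == pytest.approx(min(h["val_loss"]))
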