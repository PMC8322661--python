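import itertools

import numpy as np
import pytest

from dbnsurv.rbm import (
    RBMParams,
    TrainConfig,
    cd_k_update,
    cd_statistics,
    enumerate_joint,
    exact_gradient,
    exact_log_likelihood,
    free_energy,
    gibbs_visible_marginal,
    hidden_conditional,
    init_rbm,
    log_partition,
    reconstruction_cross_entropy,
    train_rbm,
    visible_conditional,
)


def _zero_rbm(n_vis, n_hid):
    return RBMParams(np.zeros((n_vis, n_hid)), np.zeros(n_vis), np.zeros(n_hid))


def _all_states(n):
    return np.array(list(itertools.product((0.0, 1.0), repeat=n)))


class TestConditionals:
    def test_zero_parameters_give_half(self):
        rbm = _zero_rbm(3, 4)
        v = np.array([1.0, 0.0, 1.0])
        np.testing.assert_allclose(hidden_conditional(rbm, v), 0.5)
        np.testing.assert_allclose(visible_conditional(rbm, np.zeros(4)), 0.5)

    def test_sigmoid_saturation(self):
        rbm = RBMParams(np.zeros((2, 2)), np.zeros(2), np.array([30.0, -30.0]))
        p = hidden_conditional(rbm, np.zeros(2))
        assert p[0] == pytest.approx(1.0, abs=1e-9)
        assert p[1] == pytest.approx(0.0, abs=1e-9)

    def test_worked_two_by_two_example(self):
        rbm = RBMParams(np.eye(2), np.zeros(2), np.zeros(2))
        p = hidden_conditional(rbm, np.array([1.0, 0.0]))
        np.testing.assert_allclose(p, [1 / (1 + np.exp(-1)), 0.5], atol=1e-12)

    def test_structural_symmetry_under_transpose(self, rng):
        rbm = init_rbm(4, 3, rng, scale=0.5)
        rbm.b = rng.normal(size=4)
        rbm.c = rng.normal(size=3)
        flipped = RBMParams(rbm.W.T, rbm.c, rbm.b)
        h = (rng.random(3) < 0.5).astype(float)
        np.testing.assert_allclose(
            visible_conditional(rbm, h), hidden_conditional(flipped, h)
        )

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            hidden_conditional(_zero_rbm(3, 2), np.zeros(4))


class TestFreeEnergy:
    def test_zero_parameter_closed_form(self):
        rbm = _zero_rbm(3, 4)
        assert free_energy(rbm, np.zeros(3)) == pytest.approx(-4 * np.log(2))

    def test_marginal_matches_joint_enumeration(self, rng):
        rbm = init_rbm(5, 3, rng, scale=0.8)
        rbm.b = rng.normal(size=5)
        rbm.c = rng.normal(size=3)
        joint = enumerate_joint(rbm)
        V = _all_states(5)
        pv = np.exp(-free_energy(rbm, V) - log_partition(rbm))
        np.testing.assert_allclose(pv, joint.sum(axis=1), atol=1e-12)

    def test_visible_bias_shift_is_linear(self, rng):
        rbm = init_rbm(4, 2, rng, scale=0.3)
        v = np.array([1.0, 0.0, 1.0, 1.0])
        shifted = RBMParams(rbm.W, rbm.b + 0.7, rbm.c)
        assert free_energy(shifted, v) == pytest.approx(
            free_energy(rbm, v) - 0.7 * v.sum()
        )


class TestExactLikelihood:
    def test_zero_parameters_uniform_marginal(self):
        rbm = _zero_rbm(4, 3)
        data = np.array([[0, 1, 0, 1], [1, 1, 0, 0.0]])
        assert exact_log_likelihood(rbm, data) == pytest.approx(-4 * np.log(2))

    def test_joint_normalizes(self, rng):
        for _ in range(5):
            rbm = init_rbm(4, 3, rng, scale=1.0)
            rbm.b, rbm.c = rng.normal(size=4), rng.normal(size=3)
            assert enumerate_joint(rbm).sum() == pytest.approx(1.0, abs=1e-10)

    def test_unused_hidden_unit_leaves_likelihood_unchanged(self, rng):
        rbm = init_rbm(4, 2, rng, scale=0.5)
        data = (rng.random((6, 4)) < 0.5).astype(float)
        padded = RBMParams(
            np.hstack([rbm.W, np.zeros((4, 1))]), rbm.b, np.append(rbm.c, 0.0)
        )
        # the extra unit contributes a factor 2 to both numerator and Z
        assert exact_log_likelihood(padded, data) == pytest.approx(
            exact_log_likelihood(rbm, data)
        )

    def test_refuses_oversized_model(self):
        with pytest.raises(ValueError):
            exact_log_likelihood(_zero_rbm(15, 10), np.zeros((1, 15)))


def _expected_cd1_update(rbm, data):
    """Exact expectation of the CD-1 statistics by enumerating chain states."""
    H = _all_states(rbm.n_hidden)
    V = _all_states(rbm.n_visible)
    dW = np.zeros_like(rbm.W)
    db = np.zeros_like(rbm.b)
    dc = np.zeros_like(rbm.c)
    for v0 in data:
        p_h0 = hidden_conditional(rbm, v0)
        dW += np.outer(v0, p_h0)
        db += v0
        dc += p_h0
        # enumerate h0 then v1
        p_h0_states = np.prod(np.where(H == 1, p_h0, 1 - p_h0), axis=1)
        for h0, ph in zip(H, p_h0_states):
            p_v1 = visible_conditional(rbm, h0)
            p_v1_states = np.prod(np.where(V == 1, p_v1, 1 - p_v1), axis=1)
            for v1, pv in zip(V, p_v1_states):
                w = ph * pv
                p_h1 = hidden_conditional(rbm, v1)
                dW -= w * np.outer(v1, p_h1)
                db -= w * v1
                dc -= w * p_h1
    return dW / len(data), db / len(data), dc / len(data)


class TestContrastiveDivergence:
    def test_zero_learning_rate_leaves_parameters(self, rng):
        rbm = init_rbm(4, 3, rng)
        batch = (rng.random((5, 4)) < 0.5).astype(float)
        cfg = TrainConfig(learning_rate=0.0)
        out = cd_k_update(rbm, batch, cfg, rng)
        np.testing.assert_array_equal(out.W, rbm.W)

    def test_forced_reconstruction_leaves_only_weight_decay(self, rng):
        # huge visible biases force the chain to reconstruct the all-ones batch,
        # so positive and negative statistics cancel exactly
        rbm = RBMParams(rng.normal(0, 0.1, (3, 2)), np.full(3, 30.0), np.zeros(2))
        batch = np.ones((1, 3))
        cfg = TrainConfig(learning_rate=0.5, weight_decay=0.01)
        out = cd_k_update(rbm, batch, cfg, rng)
        np.testing.assert_allclose(
            out.W, rbm.W - 0.5 * 0.01 * rbm.W, atol=1e-9
        )

    def test_sampled_statistics_unbiased_for_expected_update(self, rng):
        rbm = init_rbm(3, 2, rng, scale=0.3)
        data = (rng.random((4, 3)) < 0.5).astype(float)
        exp_dW, exp_db, exp_dc = _expected_cd1_update(rbm, data)
        n = 4000
        draws = np.array([cd_statistics(rbm, data, 1, rng)[0] for _ in range(n)])
        se = draws.std(axis=0, ddof=1) / np.sqrt(n)
        assert np.all(np.abs(draws.mean(axis=0) - exp_dW) < 4 * se + 1e-12)

    def test_expected_update_aligned_with_exact_gradient(self, rng):
        # CD-1's expected direction should almost always ascend the likelihood
        hits = 0
        for _ in range(100):
            rbm = init_rbm(3, 2, rng, scale=0.4)
            rbm.b = rng.normal(0, 0.3, 3)
            rbm.c = rng.normal(0, 0.3, 2)
            data = (rng.random((5, 3)) < rng.random(3)).astype(float)
            cd = np.concatenate([g.ravel() for g in _expected_cd1_update(rbm, data)])
            ex = np.concatenate([g.ravel() for g in exact_gradient(rbm, data)])
            hits += np.dot(cd, ex) > 0
        assert hits >= 95


class TestTrainRBM:
    def test_likelihood_improves_on_two_patterns(self, rng):
        pats = np.array([[1, 1, 1, 0, 0, 0], [0, 0, 0, 1, 1, 1.0]])
        data = pats[rng.integers(0, 2, 60)]
        cfg = TrainConfig(epochs=500, seed=0, batch_size=25)
        before = exact_log_likelihood(init_rbm(6, 4, np.random.default_rng(0)), data)
        rbm = train_rbm(data, 4, cfg)
        after = exact_log_likelihood(rbm, data)
        assert after > before
        assert reconstruction_cross_entropy(rbm, data) <= reconstruction_cross_entropy(
            init_rbm(6, 4, np.random.default_rng(0)), data
        )

    def test_bitwise_determinism(self, rng):
        data = (rng.random((30, 5)) < 0.4).astype(float)
        cfg = TrainConfig(epochs=20, seed=7)
        a = train_rbm(data, 3, cfg)
        b = train_rbm(data, 3, cfg)
        assert (a.W == b.W).all() and (a.b == b.b).all() and (a.c == b.c).all()

    def test_empty_data_raises(self):
        with pytest.raises(ValueError):
            train_rbm(np.empty((0, 4)), 3, TrainConfig(epochs=1))


def test_gibbs_marginal_matches_enumeration(rng):
    rbm = init_rbm(4, 3, rng, scale=0.6)
    rbm.b = rng.normal(0, 0.5, 4)
    joint = enumerate_joint(rbm)
    pv = dict(zip(map(tuple, _all_states(4).astype(int)), joint.sum(axis=1)))
    emp = gibbs_visible_marginal(rbm, n_steps=100_000, rng=np.random.default_rng(0))
    tv = 0.5 * sum(abs(emp.get(k, 0.0) - p) for k, p in pv.items())
    assert tv < 0.02
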