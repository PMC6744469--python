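"""Network forward/gradient correctness and SCG training behavior.

The finite-difference comparison is the core correctness oracle for the
backpropagation code; the linear-network case additionally has the
closed-form least-squares solution as an independent check.
"""

import numpy as np
import pytest

from oxinet.ann import (MinMaxNorm, MLPModel, TrainingConfig, fit_normalization,
                        init_model, scg_train)


def identity_norms(d_in: int):
    return (MinMaxNorm(lo=-np.ones(d_in), hi=np.ones(d_in)),
            MinMaxNorm(lo=np.array([-1.0]), hi=np.array([1.0])))


def finite_difference_gradient(model, X, T, eps=1e-6):
    theta = model.get_flat()
    fd = np.empty_like(theta)
    for i in range(theta.size):
        tp = theta.copy()
        tp[i] += eps
        model.set_flat(tp)
        lp = model.mse_loss(X, T)
        tm = theta.copy()
        tm[i] -= eps
        model.set_flat(tm)
        lm = model.mse_loss(X, T)
        fd[i] = (lp - lm) / (2 * eps)
    model.set_flat(theta)
    return fd


class TestInit:
    def test_same_seed_identical(self):
        a, b = init_model((10, 4, 1), seed=3), init_model((10, 4, 1), seed=3)
        for wa, wb in zip(a.weights, b.weights):
            np.testing.assert_array_equal(wa, wb)

    def test_different_seeds_differ(self):
        a, b = init_model((10, 4, 1), seed=3), init_model((10, 4, 1), seed=4)
        assert any((wa != wb).any() for wa, wb in zip(a.weights, b.weights))

    def test_reference_architecture_shapes(self):
        m = init_model((300, 60, 15, 5, 1), seed=0)
        assert [w.shape for w in m.weights] == [(60, 300), (15, 60), (5, 15), (1, 5)]
        assert all((b == 0).all() for b in m.biases)

    def test_weight_range_follows_fan_scaling(self):
        m = init_model((300, 60, 15, 5, 1), seed=0)
        for w, nin, nout in zip(m.weights, (300, 60, 15, 5), (60, 15, 5, 1)):
            r = np.sqrt(6.0 / (nin + nout))
            assert np.abs(w).max() <= r

    def test_degenerate_layer_list_rejected(self):
        with pytest.raises(ValueError):
            init_model((), seed=0)
        with pytest.raises(ValueError):
            init_model((5,), seed=0)


class TestForward:
    def test_zero_network_outputs_zero(self):
        m = init_model((6, 3, 1), seed=0)
        for w in m.weights:
            w[...] = 0.0
        out = m.forward_normalized(np.random.default_rng(0).normal(size=(4, 6)))
        np.testing.assert_array_equal(out, 0.0)

    def test_batch_equals_per_sample(self):
        m = init_model((6, 3, 1), seed=1)
        X = np.random.default_rng(1).normal(size=(5, 6))
        batch = m.forward_normalized(X)
        singles = np.vstack([m.forward_normalized(x[None]) for x in X])
        # repeated batch evaluation is bit-identical; batched vs row-by-row
        # BLAS paths may differ in the last ulp
        np.testing.assert_array_equal(batch, m.forward_normalized(X))
        np.testing.assert_allclose(batch, singles, rtol=1e-12)

    def test_wrong_input_length_rejected(self):
        m = init_model((6, 3, 1), seed=1)
        m.input_norm, m.target_norm = identity_norms(6)
        with pytest.raises(ValueError, match="length 6"):
            m.predict(np.zeros((2, 5)))

    def test_predict_clamps_negative_outputs(self):
        m = init_model((4, 1), seed=0)
        for w in m.weights:
            w[...] = 0.0
        m.biases[-1][...] = -0.5
        m.input_norm, m.target_norm = identity_norms(4)
        assert (m.predict(np.zeros((3, 4))) == 0.0).all()


class TestNormalization:
    def test_constant_feature_maps_to_zero(self):
        norm = MinMaxNorm.fit(np.full((5, 2), 97.0))
        np.testing.assert_array_equal(norm.transform(np.full((3, 2), 97.0)), 0.0)

    def test_midpoint_maps_to_zero(self):
        norm = MinMaxNorm(lo=np.array([80.0]), hi=np.array([100.0]))
        assert norm.transform(np.array([[90.0]]))[0, 0] == 0.0

    def test_round_trip(self):
        rng = np.random.default_rng(2)
        data = rng.uniform(50, 100, size=(20, 7))
        norm = MinMaxNorm.fit(data)
        np.testing.assert_allclose(norm.inverse(norm.transform(data)), data,
                                   atol=1e-12)

    def test_fitted_on_training_data_only(self):
        X = np.array([[0.0], [10.0]])
        inorm, tnorm = fit_normalization(X, np.array([0.0, 50.0]))
        assert inorm.transform(np.array([[20.0]]))[0, 0] == 3.0  # extrapolates

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MinMaxNorm.fit(np.empty((0, 3)))


class TestLossAndGradient:
    def test_perfect_prediction_zero_loss_zero_gradient(self):
        m = init_model((5, 3, 1), seed=2)
        X = np.random.default_rng(3).normal(size=(6, 5))
        T = m.forward_normalized(X)
        assert m.mse_loss(X, T) == 0.0
        np.testing.assert_array_equal(m.backprop_gradient(X, T), 0.0)

    def test_single_sample_squared_error(self):
        m = init_model((2, 1), seed=0)
        for w in m.weights:
            w[...] = 0.0
        assert m.mse_loss(np.zeros((1, 2)), np.array([2.0])) == 4.0

    def test_loss_matches_recomputation_from_forward(self):
        m = init_model((4, 3, 1), seed=5)
        rng = np.random.default_rng(5)
        X, T = rng.normal(size=(9, 4)), rng.normal(size=(9, 1))
        direct = np.mean((m.forward_normalized(X) - T) ** 2)
        assert m.mse_loss(X, T) == pytest.approx(direct, rel=1e-15)

    def test_empty_batch_rejected(self):
        m = init_model((4, 1), seed=0)
        with pytest.raises(ValueError, match="empty"):
            m.mse_loss(np.empty((0, 4)), np.empty(0))

    @pytest.mark.parametrize("trial", range(20))
    def test_gradient_matches_finite_differences(self, trial):
        rng = np.random.default_rng(100 + trial)
        n_layers = int(rng.integers(1, 4))
        sizes = [int(rng.integers(2, 7)) for _ in range(n_layers + 1)]
        m = init_model(sizes, seed=trial)
        X = rng.normal(size=(int(rng.integers(1, 9)), sizes[0]))
        T = rng.normal(size=(X.shape[0], sizes[-1]))
        g = m.backprop_gradient(X, T)
        fd = finite_difference_gradient(m, X, T)
        rel = np.linalg.norm(g - fd) / max(np.linalg.norm(fd), 1e-300)
        assert rel < 1e-6

    def test_linear_gradient_matches_normal_equation_form(self):
        # one linear layer: grad_w of mean (xw+b-t)^2 is 2 X^T (Xw+b-t) / n
        rng = np.random.default_rng(7)
        m = init_model((4, 1), seed=7)
        X, t = rng.normal(size=(12, 4)), rng.normal(size=(12, 1))
        w, b = m.weights[0], m.biases[0]
        resid = X @ w.T + b - t
        expect_w = 2.0 * (X.T @ resid).T / 12
        expect_b = 2.0 * resid.mean(axis=0)
        g = m.backprop_gradient(X, t)
        np.testing.assert_allclose(g[:4], expect_w.ravel(), rtol=1e-12)
        np.testing.assert_allclose(g[4:], expect_b, rtol=1e-12)


class TestSCG:
    def test_linear_network_reaches_least_squares(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 6))
        y = X @ rng.normal(size=6) + 0.05 * rng.normal(size=100)
        m = init_model((6, 1), seed=8)
        m.input_norm, m.target_norm = identity_norms(6)
        m, hist = scg_train(m, X, y, X, y,
                            TrainingConfig(max_iterations=500, max_val_failures=100))
        w_ls = np.linalg.lstsq(np.column_stack([X, np.ones(100)]), y, rcond=None)[0]
        fitted = np.concatenate([m.weights[0].ravel(), m.biases[0]])
        np.testing.assert_allclose(fitted, w_ls, atol=1e-6)

    def test_noiseless_realizable_target_fits_below_1e4(self):
        rng = np.random.default_rng(9)
        teacher = init_model((8, 5, 1), seed=99)
        X = rng.normal(size=(150, 8))
        y = teacher.forward_normalized(X)[:, 0]
        # over-parameterized student: the target is realizable with slack
        student = init_model((8, 12, 1), seed=10)
        student.input_norm, student.target_norm = identity_norms(8)
        student, hist = scg_train(
            student, X, y, X, y,
            TrainingConfig(max_iterations=2000, max_val_failures=2000))
        assert min(hist.train_mse) < 1e-6

    def test_best_so_far_training_mse_non_increasing_when_val_is_train(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 5))
        y = np.tanh(X @ rng.normal(size=5))
        m = init_model((5, 4, 1), seed=11)
        m.input_norm, m.target_norm = identity_norms(5)
        m, hist = scg_train(m, X, y, X, y,
                            TrainingConfig(max_iterations=200, max_val_failures=200))
        best = np.minimum.accumulate(hist.train_mse)
        assert (np.diff(best) <= 0).all()

    def test_early_stopping_halts_and_returns_best_iterate(self):
        # train and validation drawn from different linear models: the SCG
        # path to the train optimum passes a validation minimum, after
        # which validation MSE rises and plateaus
        rng = np.random.default_rng(12)
        X = rng.normal(size=(80, 4))
        y_train = X @ np.array([1.0, -2.0, 0.5, 3.0])
        Xv = rng.normal(size=(40, 4))
        y_val = Xv @ np.array([-1.0, 2.0, -0.5, -3.0])
        m = init_model((4, 1), seed=12)
        m.input_norm, m.target_norm = identity_norms(4)
        cfg = TrainingConfig(max_iterations=10000, max_val_failures=100)
        m, hist = scg_train(m, X, y_train, Xv, y_val, cfg)
        n_iter = len(hist.val_mse)
        assert n_iter < 10000, "early stopping must fire"
        assert n_iter <= hist.best_iteration + 1 + cfg.max_val_failures
        # returned parameters reproduce the best validation MSE exactly
        vxh = m.input_norm.transform(Xv)
        vth = m.target_norm.transform(y_val.reshape(-1, 1))
        assert m.mse_loss(vxh, vth) == min(hist.val_mse) == hist.best_val_mse

    def test_nan_loss_aborts_with_iteration_number(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(10, 3))
        y = np.array([np.nan] * 10)
        m = init_model((3, 1), seed=13)
        m.input_norm, m.target_norm = identity_norms(3)
        with pytest.raises(FloatingPointError, match="iteration"):
            scg_train(m, X, y, X, y, TrainingConfig(max_iterations=50))

    def test_empty_sets_rejected(self):
        m = init_model((3, 1), seed=0)
        m.input_norm, m.target_norm = identity_norms(3)
        with pytest.raises(ValueError, match="empty training"):
            scg_train(m, np.empty((0, 3)), np.empty(0), np.zeros((1, 3)),
                      np.zeros(1))


class TestSerialization:
    def test_round_trip_is_bit_exact(self, tmp_path):
        m = init_model((12, 6, 3, 1), seed=21)
        m.input_norm, m.target_norm = fit_normalization(
            np.random.default_rng(21).uniform(70, 100, size=(30, 12)),
            np.random.default_rng(22).uniform(0, 90, size=30))
        path = tmp_path / "model.json"
        m.save(path)
        back = MLPModel.load(path)
        for wa, wb in zip(m.weights, back.weights):
            assert wa.tobytes() == wb.tobytes()
        for ba, bb in zip(m.biases, back.biases):
            assert ba.tobytes() == bb.tobytes()
        assert back.input_norm.lo.tobytes() == m.input_norm.lo.tobytes()
        X = np.random.default_rng(23).uniform(70, 100, size=(5, 12))
        np.testing.assert_array_equal(m.predict(X), back.predict(X))

    def test_unknown_schema_rejected(self):
        m = init_model((3, 1), seed=0)
        d = m.to_dict()
        d["schema"] = 999
        with pytest.raises(ValueError, match="schema"):
            MLPModel.from_dict(d)
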