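"""Training algorithms: LM, SCG, Rprop and the delta-rule baseline."""

import numpy as np
import pytest

from ppgavf.mlp import forward, init_weights, mse_loss
from ppgavf.trainers import (
    TrainConfig,
    levenberg_marquardt,
    scg_minimize,
    train,
    train_gd,
    train_lm,
    train_rprop,
    train_scg,
)

XOR_X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
XOR_T = np.array([[0.0], [1.0], [1.0], [0.0]])


def blob_dataset(seed=0, n_per_class=6):
    """Well-separated 3-class points in 4-D with one-hot targets."""
    rng = np.random.default_rng(seed)
    centers = np.array(
        [[0.2, 0.2, 0.1, 0.1], [0.5, 0.6, 0.3, 0.3], [0.9, 0.9, 0.8, 0.7]]
    )
    x, t = [], []
    for c, center in enumerate(centers):
        x.append(center + 0.03 * rng.standard_normal((n_per_class, 4)))
        hot = np.zeros(3)
        hot[c] = 1
        t.append(np.tile(hot, (n_per_class, 1)))
    return np.vstack(x), np.vstack(t)


class TestLevenbergMarquardt:
    def test_linear_least_squares_in_three_iterations(self):
        rng = np.random.default_rng(42)
        A = rng.normal(size=(20, 6))
        b = rng.normal(size=20)
        x_star = np.linalg.lstsq(A, b, rcond=None)[0]
        f_star = float(np.mean((b - A @ x_star) ** 2))
        opt = levenberg_marquardt(
            lambda x: b - A @ x,
            lambda x: -A,
            np.zeros(6),
            error_goal=f_star * (1 + 1e-10) + 1e-12,
            max_iter=50,
        )
        assert opt.stop_reason == "error_goal"
        assert opt.iterations <= 3
        assert np.max(np.abs(opt.x - x_star)) < 1e-8

    def test_xor_benchmark_majority_of_seeds(self):
        successes = 0
        for seed in range(10):
            model = init_weights(2, 2, 1, seed=seed)
            result = train_lm(model, XOR_X, XOR_T, TrainConfig(algorithm="lm"))
            successes += result.final_mse < 1e-3
        assert successes >= 8

    def test_large_damping_follows_negative_gradient(self):
        from ppgavf.mlp import error_jacobian

        m = init_weights(4, 5, 3, seed=1)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(6, 4))
        t = rng.uniform(size=(6, 3))
        J, e = error_jacobian(m, x, t)
        g = J.T @ e
        mu = 1e8
        step = np.linalg.solve(J.T @ J + mu * np.eye(g.size), g)
        cos = step @ g / (np.linalg.norm(step) * np.linalg.norm(g))
        assert np.degrees(np.arccos(min(cos, 1.0))) < 1.0

    def test_accepted_steps_never_increase_mse(self):
        x, t = blob_dataset(3)
        result = train_lm(init_weights(4, 8, 3, seed=3), x, t)
        hist = np.array(result.mse_history)
        assert np.all(np.diff(hist) <= 0)

    def test_singular_system_stops_with_mu_overflow(self):
        # a residual that cannot decrease: constant function of x
        opt = levenberg_marquardt(
            lambda x: np.ones(3),
            lambda x: np.zeros((3, 2)),
            np.zeros(2),
            error_goal=1e-9,
            max_iter=50,
        )
        assert opt.stop_reason == "mu_overflow"


class TestScg:
    def test_quadratic_converges_within_n_plus_five(self):
        rng = np.random.default_rng(0)
        n = 10
        G = rng.normal(size=(n, n))
        Q = G @ G.T + n * np.eye(n)
        c = rng.normal(size=n)
        x_star = np.linalg.solve(Q, c)
        opt = scg_minimize(
            lambda x: (0.5 * x @ Q @ x - c @ x, Q @ x - c),
            np.zeros(n),
            error_goal=-np.inf,
            max_iter=n + 5,
            min_gradient=0.0,
        )
        assert np.max(np.abs(opt.x - x_star)) < 1e-6

    def test_zero_gradient_start_stops_immediately(self):
        opt = scg_minimize(
            lambda x: (float(x @ x), 2 * x), np.zeros(4), error_goal=-1.0, max_iter=100
        )
        assert opt.iterations == 0
        assert opt.stop_reason == "min_gradient"

    def test_beats_gradient_descent_at_equal_budget(self):
        wins = 0
        for seed in range(10):
            x, t = blob_dataset(seed)
            cfg_scg = TrainConfig(algorithm="scg", max_epochs=50, error_goal=1e-12)
            cfg_gd = TrainConfig(algorithm="gd", max_epochs=50, error_goal=1e-12, momentum=0.0)
            m = init_weights(4, 8, 3, seed=seed)
            scg_mse = train_scg(m, x, t, cfg_scg).final_mse
            gd_mse = train_gd(m, x, t, cfg_gd).final_mse
            wins += scg_mse <= gd_mse
        assert wins > 5


class TestRprop:
    def test_step_grows_geometrically_under_constant_sign(self):
        from ppgavf.trainers import rprop_minimize

        # f(w) = w: the gradient is +1 forever, so the step size must grow
        # by eta_plus each iteration until delta_max
        log = []
        rprop_minimize(
            lambda w: (float(w[0]), np.ones(1)),
            np.zeros(1),
            error_goal=-np.inf,
            max_iter=12,
            delta0=0.1,
            eta_plus=1.2,
            delta_max=1.0,
            state_log=log,
        )
        steps = [s.step[0] for s in log]
        expected = [min(0.1 * 1.2**i, 1.0) for i in range(12)]
        assert steps == pytest.approx(expected)

    def test_sign_flip_shrinks_step_toward_minimum(self):
        from ppgavf.trainers import rprop_minimize

        # |w|-shaped valley narrower than the initial step: the gradient sign
        # flips every iteration, so the step must shrink toward delta_min
        log = []
        rprop_minimize(
            lambda w: (abs(float(w[0])), np.sign(w) + (w == 0)),
            np.full(1, 1e-9),
            error_goal=-np.inf,
            max_iter=40,
            delta0=0.5,
            eta_minus=0.5,
            delta_min=1e-6,
            state_log=log,
        )
        steps = np.array([s.step[0] for s in log])
        assert steps[-1] == pytest.approx(1e-6)
        # shrinking happens on flips only; the sequence is non-increasing
        # once oscillation sets in
        assert np.all(np.diff(steps[1:]) <= 1e-12)

    def test_trainer_applies_sign_rules(self):
        # quadratic bowl in network disguise is overkill; verify on the MLP
        # that step sizes stay within bounds and MSE improves
        x, t = blob_dataset(1)
        result = train_rprop(init_weights(4, 8, 3, seed=1), x, t)
        assert result.final_mse < result.mse_history[0]
        assert result.stop_reason in {"error_goal", "max_epochs"}

    def test_faster_than_gradient_descent(self):
        wins = 0
        for seed in range(10):
            x, t = blob_dataset(seed)
            m = init_weights(4, 8, 3, seed=seed)
            ep_rprop = train_rprop(m, x, t, TrainConfig(algorithm="rprop")).epochs
            ep_gd = train_gd(m, x, t, TrainConfig(algorithm="gd")).epochs
            wins += ep_rprop <= ep_gd
        assert wins > 5


class TestGradientDescent:
    def test_single_step_matches_hand_computed_delta_rule(self):
        m = init_weights(2, 2, 1, seed=4)
        x = np.array([[1.0, -0.5]])
        t = np.array([[1.0]])
        cfg = TrainConfig(algorithm="gd", lr=0.1, momentum=0.0, max_epochs=1, error_goal=1e-30)
        result = train_gd(m, x, t, cfg)
        # hand computation of eta * y_j * delta_k for the output layer
        y, state = forward(m, x)
        delta_k = y * (1 - y) * (t - y)
        expected_w_out = m.w_out + 0.1 * delta_k.T @ state.y_hidden
        assert np.allclose(result.model.w_out, expected_w_out, atol=1e-12)
        # hidden layer via back-propagated delta
        delta_j = (delta_k @ m.w_out) * state.y_hidden * (1 - state.y_hidden)
        expected_w_hidden = m.w_hidden + 0.1 * delta_j.T @ x
        assert np.allclose(result.model.w_hidden, expected_w_hidden, atol=1e-12)

    def test_zero_learning_rate_freezes_weights(self):
        x, t = blob_dataset(0)
        m = init_weights(4, 8, 3, seed=0)
        result = train_gd(m, x, t, TrainConfig(algorithm="gd", lr=0.0, max_epochs=5))
        assert np.array_equal(result.model.get_params(), m.get_params())

    def test_zero_momentum_is_pure_delta_rule(self):
        x, t = blob_dataset(0)
        m = init_weights(4, 8, 3, seed=0)
        cfg = TrainConfig(algorithm="gd", momentum=0.0, max_epochs=3, error_goal=1e-30)
        r1 = train_gd(m, x, t, cfg)
        # manual two applications of single steps must agree with one 2-epoch run
        cfg1 = TrainConfig(algorithm="gd", momentum=0.0, max_epochs=1, error_goal=1e-30)
        step1 = train_gd(m, x, t, cfg1)
        step2 = train_gd(step1.model, x, t, cfg1)
        cfg2 = TrainConfig(algorithm="gd", momentum=0.0, max_epochs=2, error_goal=1e-30)
        two = train_gd(m, x, t, cfg2)
        assert np.allclose(step2.model.get_params(), two.model.get_params(), atol=1e-12)


class TestStoppingContract:
    @pytest.mark.parametrize("algorithm", ["lm", "scg", "rprop", "gd"])
    def test_already_satisfied_goal_is_noop(self, algorithm):
        x, t = blob_dataset(0)
        m = init_weights(4, 8, 3, seed=0)
        y, _ = forward(m, x)
        goal = mse_loss(y, t) + 1.0  # already satisfied
        cfg = TrainConfig(algorithm=algorithm, error_goal=goal)
        result = train(m, x, t, cfg)
        assert result.epochs == 0
        assert result.stop_reason == "error_goal"
        assert np.array_equal(result.model.get_params(), m.get_params())

    @pytest.mark.parametrize("algorithm", ["lm", "scg", "rprop", "gd"])
    def test_bit_reproducible(self, algorithm):
        x, t = blob_dataset(2)
        cfg = TrainConfig(algorithm=algorithm, max_epochs=30, error_goal=1e-9)
        r1 = train(init_weights(4, 8, 3, seed=2), x, t, cfg)
        r2 = train(init_weights(4, 8, 3, seed=2), x, t, cfg)
        assert np.array_equal(r1.model.get_params(), r2.model.get_params())
        assert r1.mse_history == r2.mse_history
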