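"""Network training algorithms: Levenberg–Marquardt, SCG, Rprop, delta rule.

All four trainers are full-batch and share one stopping contract: training
ends when the MSE reaches the error goal (1e-3 by default), when the epoch
budget (1000) is exhausted, or on an algorithm-specific condition (damping
overflow for LM, vanishing gradient for SCG).  A trainer invoked on a model
that already satisfies the goal returns it unchanged after zero epochs.

The two curvature-aware methods are implemented as generic optimisers —
:func:`levenberg_marquardt` over a residual/Jacobian pair and
:func:`scg_minimize` over a value/gradient pair — and wrapped for the MLP.
LM iterates the damped Gauss–Newton update

    x_{k+1} = x_k - (J^T J + mu I)^{-1} J^T e,

solving the damped normal equations with a Cholesky factorisation (never an
explicit inverse), decreasing mu after an accepted step and increasing it
after a rejected one, so the accepted-step loss is strictly decreasing.
SCG is Møller's scaled conjugate gradient: conjugate search directions with
a second-order step length estimated from a finite-difference curvature
probe (sigma) and a Levenberg-style scale lambda that enforces positive
curvature, avoiding any line search.  Rprop adapts a per-weight step size
from the sign history of the gradient (grow on agreement, shrink and
retract on a flip) and moves by ``-sign(gradient) * step``.  The plain
delta rule with learning rate and momentum is the baseline the three main
algorithms are compared against; it is the only trainer that uses the
published learning-rate/momentum pair, which the others do not need by
construction.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import linalg

from .mlp import MlpModel, error_jacobian, forward, gradients, mse_loss

__all__ = [
    "TrainConfig",
    "TrainResult",
    "OptResult",
    "RpropState",
    "levenberg_marquardt",
    "scg_minimize",
    "rprop_minimize",
    "train_lm",
    "train_scg",
    "train_rprop",
    "train_gd",
    "train",
]

ALGORITHMS = ("lm", "scg", "rprop", "gd")


@dataclass(frozen=True)
class TrainConfig:
    """Shared and per-algorithm training parameters (published defaults)."""

    algorithm: str = "lm"
    lr: float = 0.1  # delta-rule learning rate
    error_goal: float = 1e-3  # stop when MSE <= error_goal
    max_epochs: int = 1000
    momentum: float = 0.95  # delta-rule momentum
    seed: int = 0
    # Levenberg-Marquardt damping schedule
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 10.0
    mu_max: float = 1e10
    # Moller SCG constants
    sigma: float = 5e-5
    lambda0: float = 5e-7
    min_gradient: float = 1e-10
    # Rprop step-size dynamics
    delta0: float = 0.07
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta_max: float = 50.0
    delta_min: float = 1e-6
    # delta-rule divergence guard
    divergence: float = 1e6

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")
        if self.error_goal <= 0:
            raise ValueError("error_goal must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainResult:
    model: MlpModel
    epochs: int
    mse_history: list[float]
    stop_reason: str  # error_goal | max_epochs | mu_overflow | min_gradient | diverged
    train_time: float  # wall-clock seconds
    predict_time_per_sample: float

    @property
    def final_mse(self) -> float:
        return self.mse_history[-1]


@dataclass
class OptResult:
    x: np.ndarray
    iterations: int
    history: list[float]
    stop_reason: str


def levenberg_marquardt(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    jacobian_fn: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    *,
    error_goal: float = 1e-3,
    max_iter: int = 1000,
    mu0: float = 1e-3,
    mu_inc: float = 10.0,
    mu_dec: float = 10.0,
    mu_max: float = 1e10,
) -> OptResult:
    """Minimise the mean squared residual by damped Gauss–Newton steps.

    ``residual_fn(x)`` returns the residual vector e(x) and ``jacobian_fn(x)``
    its derivative de/dx.  The objective is ``mean(e**2)``.  Accepted steps
    strictly decrease the objective; a step is retried with larger damping
    until it does, and the run stops with reason ``mu_overflow`` once the
    damping exceeds ``mu_max``.
    """
    x = np.asarray(x0, dtype=float).copy()
    e = residual_fn(x)
    f = float(np.mean(e**2))
    history = [f]
    mu = mu0
    if f <= error_goal:
        return OptResult(x=x, iterations=0, history=history, stop_reason="error_goal")

    for it in range(1, max_iter + 1):
        J = jacobian_fn(x)
        g = J.T @ e
        H = J.T @ J
        accepted = False
        while not accepted:
            if mu > mu_max:
                return OptResult(x=x, iterations=it - 1, history=history, stop_reason="mu_overflow")
            A = H + mu * np.eye(H.shape[0])
            try:
                c, low = linalg.cho_factor(A)
                step = linalg.cho_solve((c, low), g)
            except linalg.LinAlgError:
                mu *= mu_inc
                continue
            x_new = x - step
            e_new = residual_fn(x_new)
            f_new = float(np.mean(e_new**2))
            if np.isfinite(f_new) and f_new < f:
                accepted = True
                x, e, f = x_new, e_new, f_new
                mu = max(mu / mu_dec, 1e-20)
            else:
                mu *= mu_inc
        history.append(f)
        if f <= error_goal:
            return OptResult(x=x, iterations=it, history=history, stop_reason="error_goal")
    return OptResult(x=x, iterations=max_iter, history=history, stop_reason="max_epochs")


def scg_minimize(
    fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    *,
    error_goal: float = 1e-3,
    max_iter: int = 1000,
    sigma0: float = 5e-5,
    lambda0: float = 5e-7,
    min_gradient: float = 1e-10,
) -> OptResult:
    """Møller's scaled conjugate gradient on a scalar objective.

    ``fun_grad(x)`` returns ``(f, grad)``.  Curvature along the search
    direction is probed with a sigma-step finite difference of the gradient
    and rescaled by lambda whenever it is not positive, so no line search is
    required.  Stops on the error goal, the iteration budget, or when the
    gradient norm falls below ``min_gradient``.
    """
    x = np.asarray(x0, dtype=float).copy()
    n = x.size
    f, g = fun_grad(x)
    r = -g  # steepest-descent residual
    d = r.copy()  # search direction
    lam, lam_bar = lambda0, 0.0
    success = True
    history = [f]
    if f <= error_goal:
        return OptResult(x=x, iterations=0, history=history, stop_reason="error_goal")
    delta = 0.0

    for it in range(1, max_iter + 1):
        norm_r = np.linalg.norm(r)
        if norm_r < min_gradient:
            return OptResult(x=x, iterations=it - 1, history=history, stop_reason="min_gradient")
        d_norm2 = float(d @ d)
        if success:
            # second-order curvature probe along d
            sigma = sigma0 / np.sqrt(d_norm2)
            _, g_plus = fun_grad(x + sigma * d)
            s = (g_plus - g) / sigma
            delta = float(d @ s)
        # scale to enforce positive definiteness
        delta += (lam - lam_bar) * d_norm2
        if delta <= 0:
            lam_bar = 2.0 * (lam - delta / d_norm2)
            delta = -delta + lam * d_norm2
            lam = lam_bar
        mu_step = float(d @ r)
        alpha = mu_step / delta
        x_new = x + alpha * d
        f_new, g_new = fun_grad(x_new)
        comparison = 2.0 * delta * (f - f_new) / (mu_step**2)
        if comparison >= 0:
            # accepted step
            x, f = x_new, f_new
            g_old, g = g, g_new
            r_new = -g
            lam_bar = 0.0
            success = True
            history.append(f)
            if f <= error_goal:
                return OptResult(x=x, iterations=it, history=history, stop_reason="error_goal")
            if it % n == 0:
                d = r_new.copy()  # periodic restart along steepest descent
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu_step
                d = r_new + beta * d
            r = r_new
            if comparison >= 0.75:
                lam = max(lam / 4.0, 1e-300)
        else:
            lam_bar = lam
            success = False
            history.append(f)
        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / d_norm2
        if not np.isfinite(lam) or lam > 1e300:
            return OptResult(x=x, iterations=it, history=history, stop_reason="min_gradient")
    return OptResult(x=x, iterations=max_iter, history=history, stop_reason="max_epochs")


def _mlp_residual_jacobian(model: MlpModel, x: np.ndarray, t: np.ndarray):
    def residual(params: np.ndarray) -> np.ndarray:
        y, _ = forward(model.with_params(params), x)
        return (t - y).ravel()

    def jacobian(params: np.ndarray) -> np.ndarray:
        J, _ = error_jacobian(model.with_params(params), x, t)
        return J

    return residual, jacobian


def _timed(fn):
    t0 = time.perf_counter()
    out = fn()
    return out, time.perf_counter() - t0


def _predict_time(model: MlpModel, x: np.ndarray) -> float:
    (_, dt) = _timed(lambda: forward(model, x))
    return dt / max(1, np.atleast_2d(x).shape[0])


def train_lm(model: MlpModel, x: np.ndarray, targets: np.ndarray, config: TrainConfig | None = None) -> TrainResult:
    """Levenberg–Marquardt training of an MLP (damped Gauss–Newton)."""
    config = config or TrainConfig(algorithm="lm")
    residual, jacobian = _mlp_residual_jacobian(model, x, targets)
    opt, dt = _timed(
        lambda: levenberg_marquardt(
            residual,
            jacobian,
            model.get_params(),
            error_goal=config.error_goal,
            max_iter=config.max_epochs,
            mu0=config.mu0,
            mu_inc=config.mu_inc,
            mu_dec=config.mu_dec,
            mu_max=config.mu_max,
        )
    )
    final = model.with_params(opt.x)
    return TrainResult(
        model=final,
        epochs=opt.iterations,
        mse_history=opt.history,
        stop_reason=opt.stop_reason,
        train_time=dt,
        predict_time_per_sample=_predict_time(final, x),
    )


def train_scg(model: MlpModel, x: np.ndarray, targets: np.ndarray, config: TrainConfig | None = None) -> TrainResult:
    """Scaled-conjugate-gradient training of an MLP."""
    config = config or TrainConfig(algorithm="scg")

    def fun_grad(params: np.ndarray) -> tuple[float, np.ndarray]:
        m = model.with_params(params)
        y, _ = forward(m, x)
        return mse_loss(y, targets), gradients(m, x, targets)

    opt, dt = _timed(
        lambda: scg_minimize(
            fun_grad,
            model.get_params(),
            error_goal=config.error_goal,
            max_iter=config.max_epochs,
            sigma0=config.sigma,
            lambda0=config.lambda0,
            min_gradient=config.min_gradient,
        )
    )
    final = model.with_params(opt.x)
    return TrainResult(
        model=final,
        epochs=opt.iterations,
        mse_history=opt.history,
        stop_reason=opt.stop_reason,
        train_time=dt,
        predict_time_per_sample=_predict_time(final, x),
    )


@dataclass
class RpropState:
    """Per-weight step sizes and sign history, exposed for inspection."""

    step: np.ndarray
    g_prev: np.ndarray
    dx_prev: np.ndarray


def rprop_minimize(
    fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    *,
    error_goal: float = 1e-3,
    max_iter: int = 1000,
    delta0: float = 0.07,
    eta_plus: float = 1.2,
    eta_minus: float = 0.5,
    delta_max: float = 50.0,
    delta_min: float = 1e-6,
    state_log: list[RpropState] | None = None,
) -> OptResult:
    """Rprop with weight backtracking on a scalar objective.

    Per weight: the step size grows by ``eta_plus`` when the gradient keeps
    its sign, shrinks by ``eta_minus`` when it flips (and the previous move
    is retracted), and the update is ``-sign(gradient) * step``.  When
    ``state_log`` is given, the adaptation state after every iteration is
    appended to it.
    """
    x = np.asarray(x0, dtype=float).copy()
    f, _ = fun_grad(x)
    history = [f]
    if f <= error_goal:
        return OptResult(x=x, iterations=0, history=history, stop_reason="error_goal")

    step = np.full(x.size, delta0)
    g_prev = np.zeros(x.size)
    dx_prev = np.zeros(x.size)
    reason, iterations = "max_epochs", max_iter
    for it in range(1, max_iter + 1):
        _, g = fun_grad(x)
        sign_change = g * g_prev
        grown = sign_change > 0
        flipped = sign_change < 0
        step[grown] = np.minimum(step[grown] * eta_plus, delta_max)
        step[flipped] = np.maximum(step[flipped] * eta_minus, delta_min)
        dx = -np.sign(g) * step
        dx[flipped] = -dx_prev[flipped]  # retract the previous move
        g = g.copy()
        g[flipped] = 0.0  # suppress a second adaptation on the same flip
        x = x + dx
        dx_prev, g_prev = dx, g
        if state_log is not None:
            state_log.append(RpropState(step.copy(), g_prev.copy(), dx_prev.copy()))
        f, _ = fun_grad(x)
        history.append(f)
        if f <= error_goal:
            reason, iterations = "error_goal", it
            break
    return OptResult(x=x, iterations=iterations, history=history, stop_reason=reason)


def train_rprop(model: MlpModel, x: np.ndarray, targets: np.ndarray, config: TrainConfig | None = None) -> TrainResult:
    """Resilient backpropagation (Rprop with weight backtracking)."""
    config = config or TrainConfig(algorithm="rprop")

    def fun_grad(params: np.ndarray) -> tuple[float, np.ndarray]:
        m = model.with_params(params)
        y, _ = forward(m, x)
        return mse_loss(y, targets), gradients(m, x, targets)

    opt, dt = _timed(
        lambda: rprop_minimize(
            fun_grad,
            model.get_params(),
            error_goal=config.error_goal,
            max_iter=config.max_epochs,
            delta0=config.delta0,
            eta_plus=config.eta_plus,
            eta_minus=config.eta_minus,
            delta_max=config.delta_max,
            delta_min=config.delta_min,
        )
    )
    final = model.with_params(opt.x)
    return TrainResult(
        model=final,
        epochs=opt.iterations,
        mse_history=opt.history,
        stop_reason=opt.stop_reason,
        train_time=dt,
        predict_time_per_sample=_predict_time(final, x),
    )


def train_gd(model: MlpModel, x: np.ndarray, targets: np.ndarray, config: TrainConfig | None = None) -> TrainResult:
    """Plain delta-rule backpropagation with learning rate and momentum.

    One epoch applies ``w <- w + eta * sum_p y_j delta_k + momentum * prev``
    to every layer (full batch), the reference against which the curvature-
    aware trainers are compared.
    """
    config = config or TrainConfig(algorithm="gd")
    t0 = time.perf_counter()
    current = model.with_params(model.get_params())
    y, _ = forward(current, x)
    f = mse_loss(y, targets)
    history = [f]
    if f <= config.error_goal:
        return TrainResult(current, 0, history, "error_goal", time.perf_counter() - t0,
                           _predict_time(current, x))

    velocity = np.zeros(current.n_params)
    reason = "max_epochs"
    epochs = config.max_epochs
    n_terms_scale = np.atleast_2d(targets).size / 2.0  # delta rule accumulates raw sums
    for it in range(1, config.max_epochs + 1):
        # gradients() returns grad MSE = -(2/N) * sum y_j delta_k; the delta
        # rule applies the raw accumulated update eta * sum y_j delta_k
        raw_update = -gradients(current, x, targets) * n_terms_scale
        velocity = config.lr * raw_update + config.momentum * velocity
        current = current.with_params(current.get_params() + velocity)
        y, _ = forward(current, x)
        f = mse_loss(y, targets)
        history.append(f)
        if f <= config.error_goal:
            reason, epochs = "error_goal", it
            break
        if not np.isfinite(f) or f > config.divergence:
            reason, epochs = "diverged", it
            break
    return TrainResult(current, epochs, history, reason, time.perf_counter() - t0,
                       _predict_time(current, x))


_TRAINERS = {"lm": train_lm, "scg": train_scg, "rprop": train_rprop, "gd": train_gd}


def train(model: MlpModel, x: np.ndarray, targets: np.ndarray, config: TrainConfig) -> TrainResult:
    """Dispatch to the trainer named by ``config.algorithm``."""
    return _TRAINERS[config.algorithm](model, x, targets, config)
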