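"""Feed-forward multilayer perceptron core: forward pass, loss, gradients.

The classifier is a fully connected 4-35-3 network with logistic-sigmoid
activation at both the hidden and the output layer.  The four inputs are the
selected pulse-slope statistics; the three outputs are per-class scores
decoded by arg-max.  This module is trainer-agnostic: it supplies the
forward pass, the mean-squared-error loss, the exact backpropagation
gradient, and the per-sample error Jacobian needed by Gauss–Newton-type
optimisers.

Conventions
-----------
* Error is ``e = target - output``; with this sign, the classical delta-rule
  update ``w <- w + eta * y_j * delta_k`` (with ``delta_k = y_k (1-y_k) e_k``)
  is a descent step on the squared error.
* The Jacobian ``J`` holds the derivatives of the *errors* with respect to
  the weights (one row per sample-output pair), so the loss gradient
  satisfies ``grad(MSE) = (2/N) J^T e`` with ``N`` the total number of error
  terms.
* The architecture as published omits bias terms from its layer equation;
  biases are included here by default (they are required for outputs that
  saturate near 0/1) and can be disabled with ``use_bias=False``.
* Parameters are flattened in the order ``W_hidden, b_hidden, W_out, b_out``
  (row-major).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MlpModel",
    "ForwardState",
    "init_weights",
    "forward",
    "predict_classes",
    "mse_loss",
    "gradients",
    "error_jacobian",
    "sigmoid",
]


def sigmoid(v: np.ndarray) -> np.ndarray:
    """Logistic sigmoid, numerically safe for large |v|."""
    out = np.empty_like(v, dtype=float)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


@dataclass
class MlpModel:
    """Weights of a one-hidden-layer sigmoid MLP."""

    w_hidden: np.ndarray  # (hidden_dim, input_dim)
    b_hidden: np.ndarray  # (hidden_dim,)
    w_out: np.ndarray  # (output_dim, hidden_dim)
    b_out: np.ndarray  # (output_dim,)
    use_bias: bool = True

    def __post_init__(self) -> None:
        h, r = self.w_hidden.shape
        o, h2 = self.w_out.shape
        if h2 != h or self.b_hidden.shape != (h,) or self.b_out.shape != (o,):
            raise ValueError("inconsistent layer dimensions")
        for arr in (self.w_hidden, self.b_hidden, self.w_out, self.b_out):
            if not np.all(np.isfinite(arr)):
                raise ValueError("weights must be finite")

    @property
    def input_dim(self) -> int:
        return self.w_hidden.shape[1]

    @property
    def hidden_dim(self) -> int:
        return self.w_hidden.shape[0]

    @property
    def output_dim(self) -> int:
        return self.w_out.shape[0]

    @property
    def n_params(self) -> int:
        return self.w_hidden.size + self.b_hidden.size + self.w_out.size + self.b_out.size

    def get_params(self) -> np.ndarray:
        """Flat parameter vector (W_hidden, b_hidden, W_out, b_out)."""
        return np.concatenate(
            [self.w_hidden.ravel(), self.b_hidden, self.w_out.ravel(), self.b_out]
        )

    def with_params(self, vec: np.ndarray) -> "MlpModel":
        """Copy of the model with parameters taken from a flat vector."""
        vec = np.asarray(vec, dtype=float)
        if vec.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {vec.size}")
        h, r, o = self.hidden_dim, self.input_dim, self.output_dim
        i0 = h * r
        i1 = i0 + h
        i2 = i1 + o * h
        return MlpModel(
            w_hidden=vec[:i0].reshape(h, r).copy(),
            b_hidden=vec[i0:i1].copy(),
            w_out=vec[i1:i2].reshape(o, h).copy(),
            b_out=vec[i2:].copy(),
            use_bias=self.use_bias,
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "input_dim": self.input_dim,
            "hidden_dim": self.hidden_dim,
            "output_dim": self.output_dim,
            "use_bias": self.use_bias,
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MlpModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            w_hidden=np.array(payload["w_hidden"], dtype=float),
            b_hidden=np.array(payload["b_hidden"], dtype=float),
            w_out=np.array(payload["w_out"], dtype=float),
            b_out=np.array(payload["b_out"], dtype=float),
            use_bias=bool(payload["use_bias"]),
        )


@dataclass
class ForwardState:
    """Intermediate quantities of one forward pass (per sample)."""

    x: np.ndarray  # (n, input_dim)
    v_hidden: np.ndarray  # (n, hidden_dim) pre-activations
    y_hidden: np.ndarray  # (n, hidden_dim)
    v_out: np.ndarray  # (n, output_dim)
    y_out: np.ndarray  # (n, output_dim)


def init_weights(
    input_dim: int = 4,
    hidden_dim: int = 35,
    output_dim: int = 3,
    seed: int = 0,
    use_bias: bool = True,
) -> MlpModel:
    """Seeded uniform initialisation with layer-scaled (Glorot) bounds.

    Weights are drawn from U(-b, b) with b = sqrt(6 / (fan_in + fan_out));
    biases start at zero.
    """
    if min(input_dim, hidden_dim, output_dim) < 1:
        raise ValueError("all layer dimensions must be positive")
    rng = np.random.default_rng(seed)
    b1 = np.sqrt(6.0 / (input_dim + hidden_dim))
    b2 = np.sqrt(6.0 / (hidden_dim + output_dim))
    return MlpModel(
        w_hidden=rng.uniform(-b1, b1, size=(hidden_dim, input_dim)),
        b_hidden=np.zeros(hidden_dim),
        w_out=rng.uniform(-b2, b2, size=(output_dim, hidden_dim)),
        b_out=np.zeros(output_dim),
        use_bias=use_bias,
    )


def _as_batch(x: np.ndarray, dim: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.ndim != 2 or x.shape[1] != dim:
        raise ValueError(f"input must have {dim} features, got shape {x.shape}")
    return x


def forward(model: MlpModel, x: np.ndarray) -> tuple[np.ndarray, ForwardState]:
    """Network outputs y_k = sigma(v_k) for a batch of inputs."""
    x = _as_batch(x, model.input_dim)
    b1 = model.b_hidden if model.use_bias else 0.0
    b2 = model.b_out if model.use_bias else 0.0
    v1 = x @ model.w_hidden.T + b1
    y1 = sigmoid(v1)
    v2 = y1 @ model.w_out.T + b2
    y2 = sigmoid(v2)
    return y2, ForwardState(x=x, v_hidden=v1, y_hidden=y1, v_out=v2, y_out=y2)


def predict_classes(model: MlpModel, x: np.ndarray) -> np.ndarray:
    """Arg-max decoding of the output scores into class labels 1..output_dim.

    Ties break toward the lower class index.
    """
    y, _ = forward(model, x)
    return np.argmax(y, axis=1) + 1


def mse_loss(outputs: np.ndarray, targets: np.ndarray) -> float:
    """Mean of squared errors over all samples and output units."""
    outputs = np.asarray(outputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if outputs.shape != targets.shape:
        raise ValueError(f"shape mismatch: {outputs.shape} vs {targets.shape}")
    return float(np.mean((targets - outputs) ** 2))


def _deltas(model: MlpModel, state: ForwardState, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Output errors and layer deltas: e, delta_out = y'(v) e, delta_hidden."""
    e = targets - state.y_out
    d_out = state.y_out * (1.0 - state.y_out) * e
    d_hidden = (d_out @ model.w_out) * state.y_hidden * (1.0 - state.y_hidden)
    return e, d_out, d_hidden


def gradients(model: MlpModel, x: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Exact gradient of the MSE loss as a flat vector (backpropagation)."""
    x = _as_batch(x, model.input_dim)
    targets = _as_batch(targets, model.output_dim)
    _, state = forward(model, x)
    _, d_out, d_hidden = _deltas(model, state, targets)
    n_terms = targets.size
    scale = -2.0 / n_terms
    g_w2 = scale * d_out.T @ state.y_hidden
    g_b2 = scale * d_out.sum(axis=0)
    g_w1 = scale * d_hidden.T @ x
    g_b1 = scale * d_hidden.sum(axis=0)
    if not model.use_bias:
        g_b1 = np.zeros_like(g_b1)
        g_b2 = np.zeros_like(g_b2)
    return np.concatenate([g_w1.ravel(), g_b1, g_w2.ravel(), g_b2])


def error_jacobian(model: MlpModel, x: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample, per-output Jacobian of the errors e = t - y.

    Returns ``(J, e)`` where ``e`` is the flattened error vector (sample-major)
    and ``J`` has shape ``(n_samples * output_dim, n_params)`` with
    ``J = d e / d params``.  The MSE gradient equals ``(2/N) J^T e``.
    """
    x = _as_batch(x, model.input_dim)
    targets = _as_batch(targets, model.output_dim)
    n = x.shape[0]
    h, r, o = model.hidden_dim, model.input_dim, model.output_dim
    _, state = forward(model, x)
    e, _, _ = _deltas(model, state, targets)

    y2p = state.y_out * (1.0 - state.y_out)  # (n, o)
    y1p = state.y_hidden * (1.0 - state.y_hidden)  # (n, h)

    # de_{pk}/dW2[k', j] = -y2'_{pk} y1_{pj} [k == k']
    J_w2 = np.zeros((n, o, o, h))
    for k in range(o):
        J_w2[:, k, k, :] = -y2p[:, [k]] * state.y_hidden
    # de_{pk}/db2[k'] = -y2'_{pk} [k == k']
    J_b2 = np.zeros((n, o, o))
    for k in range(o):
        J_b2[:, k, k] = -y2p[:, k]
    # de_{pk}/dW1[j, i] = -y2'_{pk} W2[k, j] y1'_{pj} x_{pi}
    back = y2p[:, :, None] * model.w_out[None, :, :] * y1p[:, None, :]  # (n, o, h)
    J_w1 = -np.einsum("pkj,pi->pkji", back, x)
    J_b1 = -back  # (n, o, h)
    if not model.use_bias:
        J_b1 = np.zeros_like(J_b1)
        J_b2 = np.zeros_like(J_b2)

    J = np.concatenate(
        [
            J_w1.reshape(n, o, h * r),
            J_b1.reshape(n, o, h),
            J_w2.reshape(n, o, o * h),
            J_b2.reshape(n, o, o),
        ],
        axis=2,
    ).reshape(n * o, model.n_params)
    return J, e.ravel()
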