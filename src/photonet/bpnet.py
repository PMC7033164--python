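"""Single-hidden-layer feedforward network, written from scratch.

The architecture is the classic 3-L-1 regression perceptron: a hidden layer
of ``L = (m + n)/2 + c`` nodes (c an integer constant in [1, 10]; with the
default m=3 inputs, n=1 output and c=3 this gives 5 hidden nodes), a sigmoid
hidden activation and an unbounded linear output.  Two hidden activations
are supported:

* ``tansig`` — the hyperbolic tangent, the conventional choice for inputs
  normalized to [-1, 1] (the default);
* ``logsig`` — the logistic function ``1/(1 + exp(-z))``.

Training minimises the half-sum-of-squares error ``E = 1/2 * sum_j
(Pn'_j - Pn_j)^2`` by either full-batch gradient descent
(``w <- w - eta * dE/dw``) or damped least squares (Levenberg-Marquardt),
which solves ``(J^T J + lambda I) delta = J^T r`` on the residual Jacobian
and adapts lambda by a factor of 10 on accepted/rejected steps.  Gradients
are exact analytic back-propagation; a finite-difference check lives in the
test suite.

Weights flatten to a single parameter vector (W1 row-major, b1, W2
row-major, b2), the bridge to the particle-swarm optimizer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DimensionError, DivergenceError

ACTIVATIONS = ("tansig", "logsig")


# ---------------------------------------------------------------------------
# architecture and weights
# ---------------------------------------------------------------------------

def hidden_node_count(m: int, n_out: int, c: int) -> int:
    """Hidden-layer size ``L = (m + n)/2 + c`` (floored when m+n is odd).

    ``c`` must be an integer in [1, 10].
    """
    if not (isinstance(c, (int, np.integer)) and 1 <= c <= 10):
        raise ConfigurationError(f"c must be an integer in [1, 10], got {c!r}")
    if m < 1 or n_out < 1:
        raise ConfigurationError("m and n_out must be >= 1")
    return (m + n_out) // 2 + int(c)


@dataclass(frozen=True)
class NetworkArchitecture:
    m: int = 3
    L: int = 5
    n_out: int = 1
    hidden_activation: str = "tansig"

    def __post_init__(self):
        if self.m < 1 or self.L < 1 or self.n_out < 1:
            raise ConfigurationError("m, L, n_out must all be >= 1")
        if self.hidden_activation not in ACTIVATIONS:
            raise ConfigurationError(
                f"hidden_activation must be one of {ACTIVATIONS}")

    @property
    def n_params(self) -> int:
        return self.L * self.m + self.L + self.n_out * self.L + self.n_out


@dataclass
class NetworkWeights:
    """Weight/bias tensors: W1 (L x m), b1 (L), W2 (n_out x L), b2 (n_out)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    hidden_activation: str = "tansig"

    def __post_init__(self):
        self.W1 = np.atleast_2d(np.asarray(self.W1, dtype=float))
        self.b1 = np.asarray(self.b1, dtype=float).ravel()
        self.W2 = np.atleast_2d(np.asarray(self.W2, dtype=float))
        self.b2 = np.asarray(self.b2, dtype=float).ravel()
        L, m = self.W1.shape
        n_out = self.W2.shape[0]
        if self.b1.shape != (L,) or self.W2.shape != (n_out, L) \
                or self.b2.shape != (n_out,):
            raise DimensionError("inconsistent weight/bias shapes")
        if not all(np.isfinite(a).all() for a in (self.W1, self.b1, self.W2, self.b2)):
            raise DimensionError("weights must be finite")

    @property
    def arch(self) -> NetworkArchitecture:
        return NetworkArchitecture(m=self.W1.shape[1], L=self.W1.shape[0],
                                   n_out=self.W2.shape[0],
                                   hidden_activation=self.hidden_activation)

    def copy(self) -> "NetworkWeights":
        return NetworkWeights(self.W1.copy(), self.b1.copy(),
                              self.W2.copy(), self.b2.copy(),
                              self.hidden_activation)


def init_weights(arch: NetworkArchitecture, seed: int = 0,
                 scale: float = 0.5) -> NetworkWeights:
    """Uniform [-scale, scale] initial weights from a seeded generator."""
    rng = np.random.default_rng(seed)
    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)
    return NetworkWeights(W1=u(arch.L, arch.m), b1=u(arch.L),
                          W2=u(arch.n_out, arch.L), b2=u(arch.n_out),
                          hidden_activation=arch.hidden_activation)


def flatten(weights: NetworkWeights) -> np.ndarray:
    """Parameter vector in the fixed order W1 (row-major), b1, W2, b2."""
    return np.concatenate([weights.W1.ravel(), weights.b1,
                           weights.W2.ravel(), weights.b2])


def unflatten(vector, arch: NetworkArchitecture) -> NetworkWeights:
    """Inverse of :func:`flatten` for a given architecture."""
    vector = np.asarray(vector, dtype=float).ravel()
    if vector.size != arch.n_params:
        raise DimensionError(
            f"expected {arch.n_params} parameters, got {vector.size}")
    i = 0
    def take(k, shape):
        nonlocal i
        out = vector[i:i + k].reshape(shape)
        i += k
        return out
    W1 = take(arch.L * arch.m, (arch.L, arch.m))
    b1 = take(arch.L, (arch.L,))
    W2 = take(arch.n_out * arch.L, (arch.n_out, arch.L))
    b2 = take(arch.n_out, (arch.n_out,))
    return NetworkWeights(W1, b1, W2, b2, arch.hidden_activation)


# ---------------------------------------------------------------------------
# forward pass, loss, gradient
# ---------------------------------------------------------------------------

def _activation(z: np.ndarray, kind: str):
    if kind == "tansig":
        a = np.tanh(z)
        return a, 1.0 - a * a
    if kind == "logsig":
        a = 1.0 / (1.0 + np.exp(-z))
        return a, a * (1.0 - a)
    raise ConfigurationError(f"unknown activation {kind!r}")


def _as_batch(x, m: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x.reshape(1, -1)
    if x.ndim != 2 or x.shape[1] != m:
        raise DimensionError(f"input must have {m} features, got shape {x.shape}")
    return x


def forward(weights: NetworkWeights, x) -> np.ndarray:
    """Network output(s): linear read-out of the activated hidden layer.

    ``x`` is one sample (length m) or a batch (N x m); returns (N x n_out).
    """
    X = _as_batch(x, weights.W1.shape[1])
    h, _ = _activation(X @ weights.W1.T + weights.b1, weights.hidden_activation)
    return h @ weights.W2.T + weights.b2


def _residuals(weights, X, T):
    X = _as_batch(X, weights.W1.shape[1])
    T = np.asarray(T, dtype=float).reshape(X.shape[0], -1)
    if T.shape[1] != weights.W2.shape[0]:
        raise DimensionError(
            f"targets must have {weights.W2.shape[0]} outputs, got {T.shape}")
    return forward(weights, X) - T, X, T


def loss(weights: NetworkWeights, X, T) -> float:
    """Half the sum of squared residuals over all samples and outputs."""
    r, _, _ = _residuals(weights, X, T)
    return float(0.5 * np.sum(r * r))


def mse(weights: NetworkWeights, X, T) -> float:
    """Mean squared error per sample per output (the swarm fitness scale)."""
    r, _, _ = _residuals(weights, X, T)
    return float(np.mean(r * r))


def _jacobian(weights: NetworkWeights, X):
    """Jacobian of the residual vector w.r.t. the flat parameter vector.

    Rows iterate over (sample, output) pairs in C order; columns follow the
    flatten order.  The residual Jacobian equals the output Jacobian since
    targets are constant.
    """
    X = _as_batch(X, weights.W1.shape[1])
    N = X.shape[0]
    L, m = weights.W1.shape
    n_out = weights.W2.shape[0]
    h, dh = _activation(X @ weights.W1.T + weights.b1,
                        weights.hidden_activation)
    J = np.empty((N * n_out, weights.arch.n_params))
    for k in range(n_out):
        rows = slice(k, N * n_out, n_out)
        back = weights.W2[k] * dh                       # N x L
        J[rows, :L * m] = (back[:, :, None] * X[:, None, :]).reshape(N, L * m)
        J[rows, L * m:L * m + L] = back
        W2_block = np.zeros((N, n_out * L))
        W2_block[:, k * L:(k + 1) * L] = h
        J[rows, L * m + L:L * m + L + n_out * L] = W2_block
        b2_block = np.zeros((N, n_out))
        b2_block[:, k] = 1.0
        J[rows, L * m + L + n_out * L:] = b2_block
    return J


def gradient(weights: NetworkWeights, X, T) -> np.ndarray:
    """Exact analytic gradient of the half-sum-of-squares error, flat order."""
    r, X, _ = _residuals(weights, X, T)
    return _jacobian(weights, X).T @ r.ravel()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    eta: float = 0.05          # gradient-descent step factor
    max_epochs: int = 500
    goal: float = 1e-3         # target training MSE (normalized units)
    optimizer: str = "gd"      # 'gd' (literal gradient rule) or 'lm'
    lm_lambda0: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.eta < 0:
            raise ConfigurationError("eta must be >= 0")
        if self.goal <= 0:
            raise ConfigurationError("goal must be > 0")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.optimizer not in ("gd", "lm"):
            raise ConfigurationError("optimizer must be 'gd' or 'lm'")


@dataclass
class TrainTrace:
    """Per-epoch training MSE and the convergence outcome."""

    mse: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def epochs_used(self) -> int:
        return len(self.mse)

    def epochs_to_goal(self, goal: float) -> int:
        """First epoch (1-based) at which MSE fell to ``goal``; the trace
        length if it never did (a censored count)."""
        for i, v in enumerate(self.mse):
            if v <= goal:
                return i + 1
        return len(self.mse)


def train(weights0: NetworkWeights, X, T,
          config: TrainConfig | None = None) -> tuple[NetworkWeights, TrainTrace]:
    """Full-batch training until the MSE goal or the epoch budget.

    'gd' applies the steepest-descent rule ``w <- w - eta * dE/dw`` with the
    gradient taken on the per-sample mean of the error (the summed gradient
    divided by samples x outputs), so one ``eta`` works across sample sizes.
    'lm' applies damped least squares: solve ``(J^T J + lambda I) d = J^T r``,
    accept the step (lambda /= 10) only if the loss decreases, otherwise
    retry with lambda *= 10 — so the LM trace is non-increasing.
    """
    if config is None:
        config = TrainConfig()
    w = weights0.copy()
    trace = TrainTrace()
    lam = config.lm_lambda0

    current = mse(w, X, T)
    if not np.isfinite(current):
        raise DivergenceError("non-finite loss at initial weights", epoch=0)

    for epoch in range(1, config.max_epochs + 1):
        if config.optimizer == "gd":
            n_terms = _as_batch(X, w.W1.shape[1]).shape[0] * w.W2.shape[0]
            g = gradient(w, X, T) / n_terms
            vec = flatten(w) - config.eta * g
            w = unflatten(vec, w.arch)
            current = mse(w, X, T)
        else:  # lm
            r, Xb, _ = _residuals(w, X, T)
            J = _jacobian(w, Xb)
            JtJ = J.T @ J
            Jtr = J.T @ r.ravel()
            vec = flatten(w)
            improved = False
            for _ in range(25):  # inner lambda adaptation
                try:
                    delta = np.linalg.solve(
                        JtJ + lam * np.eye(JtJ.shape[0]), Jtr)
                except np.linalg.LinAlgError:
                    lam *= 10.0
                    continue
                cand = unflatten(vec - delta, w.arch)
                cand_mse = mse(cand, X, T)
                if np.isfinite(cand_mse) and cand_mse < current:
                    w, current = cand, cand_mse
                    lam = max(lam / 10.0, 1e-12)
                    improved = True
                    break
                lam = min(lam * 10.0, 1e12)
            if not improved:
                # the full lambda sweep failed: LM is at a (numerical)
                # stationary point and later epochs would repeat verbatim
                trace.mse.append(current)
                break
        if not np.isfinite(current):
            raise DivergenceError(
                f"training diverged at epoch {epoch}", epoch=epoch)
        trace.mse.append(current)
        if current <= config.goal:
            trace.converged = True
            break
    return w, trace


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_weights(weights: NetworkWeights, path) -> None:
    arch = weights.arch
    Path(path).write_text(json.dumps({
        "m": arch.m, "L": arch.L, "n_out": arch.n_out,
        "hidden_activation": arch.hidden_activation,
        "params": flatten(weights).tolist(),
    }, indent=1), encoding="utf-8")


def load_weights(path) -> NetworkWeights:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    arch = NetworkArchitecture(m=d["m"], L=d["L"], n_out=d["n_out"],
                               hidden_activation=d["hidden_activation"])
    return unflatten(np.asarray(d["params"]), arch)
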