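"""Particle swarm optimization over flattened network-weight vectors.

The swarm follows the canonical inertia-weight update, with one uniform
random draw per particle and per dimension:

    V <- omega*V + c1*rand()*(pbest - X) + c2*rand()*(gbest - X)
    X <- X + V

Velocities are clamped to +-v_max per dimension; positions are unclamped.
Fitness is minimized; for network training it is the per-sample-per-output
mean squared error of the unflattened network on the training split.
Defaults follow common constriction-equivalent practice (omega = 0.729,
c1 = c2 = 1.49445) with a population of 110 particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .bpnet import NetworkArchitecture, mse, unflatten
from .errors import ConfigurationError, DivergenceError

FitnessFn = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class PSOConfig:
    population: int = 110
    omega: float = 0.729
    c1: float = 1.49445
    c2: float = 1.49445
    v_max: float = 0.5
    x_init_range: tuple[float, float] = (-0.5, 0.5)
    max_iters: int = 100
    seed: int = 0
    tol: float = 1e-9          # gbest improvement below which we count a stall
    patience: int = 20         # consecutive stalled iterations before stopping

    def __post_init__(self):
        if self.population < 2:
            raise ConfigurationError("population must be >= 2")
        if self.omega < 0 or self.c1 < 0 or self.c2 < 0:
            raise ConfigurationError("omega, c1, c2 must be >= 0")
        if self.v_max <= 0:
            raise ConfigurationError("v_max must be > 0")
        if self.max_iters < 1:
            raise ConfigurationError("max_iters must be >= 1")
        if self.x_init_range[1] <= self.x_init_range[0]:
            raise ConfigurationError("x_init_range must be increasing")


@dataclass
class SwarmState:
    """Positions, velocities, personal/global bests, and fitness history."""

    X: np.ndarray
    V: np.ndarray
    pbest_pos: np.ndarray
    pbest_fit: np.ndarray
    gbest_pos: np.ndarray
    gbest_fit: float
    iteration: int = 0
    history: list[float] = field(default_factory=list)
    rng: np.random.Generator | None = None


def mse_fitness(position, arch: NetworkArchitecture, X_train, T_train) -> float:
    """Swarm fitness of one particle: training MSE of the encoded network,
    averaged over samples x output neurons."""
    return mse(unflatten(position, arch), X_train, T_train)


def make_mse_fitness(arch: NetworkArchitecture, X_train, T_train) -> FitnessFn:
    """Bind architecture and training data into a position -> fitness map."""
    return lambda position: mse_fitness(position, arch, X_train, T_train)


def _evaluate(fitness: FitnessFn, X: np.ndarray) -> np.ndarray:
    fits = np.array([fitness(x) for x in X], dtype=float)
    if not np.isfinite(fits).all():
        raise DivergenceError("non-finite fitness encountered")
    return fits


def init_swarm(dim: int, config: PSOConfig, fitness: FitnessFn) -> SwarmState:
    """Seeded uniform initialization; personal bests start at the initial
    positions and the global best at the best initial particle."""
    if dim < 1:
        raise ConfigurationError("dim must be >= 1")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.x_init_range
    X = rng.uniform(lo, hi, size=(config.population, dim))
    V = rng.uniform(-config.v_max, config.v_max, size=(config.population, dim))
    fits = _evaluate(fitness, X)
    best = int(np.argmin(fits))
    state = SwarmState(X=X, V=V, pbest_pos=X.copy(), pbest_fit=fits,
                       gbest_pos=X[best].copy(), gbest_fit=float(fits[best]),
                       rng=rng)
    state.history.append(state.gbest_fit)
    return state


def step(state: SwarmState, config: PSOConfig, fitness: FitnessFn) -> SwarmState:
    """One synchronous swarm iteration (updates ``state`` in place).

    Fresh uniform draws per particle per dimension; velocity clamped to
    +-v_max; personal and global bests refreshed after the move, so the
    global-best fitness is non-increasing across steps.
    """
    rng = state.rng if state.rng is not None else np.random.default_rng(config.seed)
    shape = state.X.shape
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    state.V = (config.omega * state.V
               + config.c1 * r1 * (state.pbest_pos - state.X)
               + config.c2 * r2 * (state.gbest_pos - state.X))
    np.clip(state.V, -config.v_max, config.v_max, out=state.V)
    state.X = state.X + state.V

    fits = _evaluate(fitness, state.X)
    improved = fits < state.pbest_fit
    state.pbest_pos[improved] = state.X[improved]
    state.pbest_fit[improved] = fits[improved]
    best = int(np.argmin(state.pbest_fit))
    if state.pbest_fit[best] < state.gbest_fit:
        state.gbest_fit = float(state.pbest_fit[best])
        state.gbest_pos = state.pbest_pos[best].copy()
    state.iteration += 1
    state.history.append(state.gbest_fit)
    return state


def optimize(dim: int, config: PSOConfig,
             fitness: FitnessFn) -> tuple[np.ndarray, float, list[float]]:
    """Run the swarm for up to ``max_iters`` steps.

    Stops early once the global-best improvement stays below ``tol`` for
    ``patience`` consecutive iterations.  Returns the best-ever position,
    its fitness, and the per-iteration global-best history (including the
    initial population's best).  Fully reproducible per seed.
    """
    state = init_swarm(dim, config, fitness)
    stalled = 0
    for _ in range(config.max_iters):
        before = state.gbest_fit
        step(state, config, fitness)
        stalled = stalled + 1 if before - state.gbest_fit < config.tol else 0
        if stalled >= config.patience:
            break
    return state.gbest_pos.copy(), state.gbest_fit, list(state.history)
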