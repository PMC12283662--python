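"""Particle swarm optimization with pluggable fitness, bounds and tracing.

Classic inertia-weight PSO, minimization convention. Velocity update per
particle i at step t:

    v[t+1] = omega * v[t] + c1 * r1 * (pbest - x[t]) + c2 * r2 * (gbest - x[t])
    x[t+1] = x[t] + v[t+1]

with r1, r2 drawn independently per particle and per dimension in (0, 1).
Positions are clipped to the search bounds and velocities to
``v_max_frac`` of the bound span per dimension (the usual v_max rule,
default 20% of the range); the clamp keeps the swarm stable — and still
able to exploit, not just bounce between walls — even for learning
factors outside the classical stability region (c1 + c2 > 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PsoConfig", "SwarmState", "pso_init", "pso_step", "pso_optimize"]


@dataclass(frozen=True)
class PsoConfig:
    """Swarm hyperparameters.

    c1, c2 : cognitive and social learning factors (>= 0).
    omega : inertia weight; larger favours global exploration. Default 0.7
        (a mid value in the commonly tuned range 0.4-0.9).
    bounds : per-dimension (lo, hi) search box.
    per_dimension_rand : draw r1/r2 per dimension (default) or one scalar
        per particle.
    """

    bounds: tuple
    n_particles: int = 10
    n_iters: int = 100
    c1: float = 1.7
    c2: float = 1.7
    omega: float = 0.7
    seed: int = 0
    per_dimension_rand: bool = True
    v_max_frac: float = 0.2



    def __post_init__(self):
        if self.n_particles < 1 or self.n_iters < 1:
            raise ValueError("n_particles and n_iters must be >= 1")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be non-negative")
        if not (0.0 < self.v_max_frac <= 1.0):
            raise ValueError("v_max_frac must lie in (0, 1]")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"invalid bound ({lo}, {hi})")

    @property
    def ndim(self) -> int:
        return len(self.bounds)

    @property
    def lo(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds], dtype=float)

    @property
    def hi(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds], dtype=float)


@dataclass
class SwarmState:
    """Positions, velocities, personal/global bests and the gbest trace."""

    positions: np.ndarray
    velocities: np.ndarray
    pbest_pos: np.ndarray
    pbest_fit: np.ndarray
    gbest_pos: np.ndarray
    gbest_fit: float
    trace: list = field(default_factory=list)


def _evaluate(fitness, positions: np.ndarray) -> np.ndarray:
    """Fitness per particle; non-finite values become +inf (candidate rejected)."""
    vals = np.array([float(fitness(p)) for p in positions])
    vals[~np.isfinite(vals)] = np.inf
    return vals


def pso_init(
    fitness, cfg: PsoConfig, rng: np.random.Generator, x0: np.ndarray | None = None
) -> SwarmState:
    """Uniform-random positions inside the bounds, zero initial velocities.

    ``x0`` (k, ndim) optionally seeds the first k particles with known
    candidate solutions (clipped to the bounds); the rest stay random.
    """
    lo, hi = cfg.lo, cfg.hi
    pos = rng.uniform(lo, hi, size=(cfg.n_particles, cfg.ndim))
    if x0 is not None:
        x0 = np.atleast_2d(np.asarray(x0, dtype=float))
        k = min(len(x0), cfg.n_particles)
        pos[:k] = np.clip(x0[:k], lo, hi)
    vel = np.zeros_like(pos)
    fit = _evaluate(fitness, pos)
    best = int(np.argmin(fit))
    state = SwarmState(
        positions=pos,
        velocities=vel,
        pbest_pos=pos.copy(),
        pbest_fit=fit.copy(),
        gbest_pos=pos[best].copy(),
        gbest_fit=float(fit[best]),
    )
    state.trace.append(state.gbest_fit)
    return state


def pso_step(
    state: SwarmState, cfg: PsoConfig, fitness, rng: np.random.Generator
) -> SwarmState:
    """One synchronous swarm update (in place; returns the state)."""
    n, d = state.positions.shape
    shape = (n, d) if cfg.per_dimension_rand else (n, 1)
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)

    v = (
        cfg.omega * state.velocities
        + cfg.c1 * r1 * (state.pbest_pos - state.positions)
        + cfg.c2 * r2 * (state.gbest_pos - state.positions)
    )
    v_max = cfg.v_max_frac * (cfg.hi - cfg.lo)
    v = np.clip(v, -v_max, v_max)
    x = np.clip(state.positions + v, cfg.lo, cfg.hi)

    fit = _evaluate(fitness, x)
    improved = fit < state.pbest_fit
    state.pbest_pos[improved] = x[improved]
    state.pbest_fit[improved] = fit[improved]
    best = int(np.argmin(state.pbest_fit))
    if state.pbest_fit[best] < state.gbest_fit:
        state.gbest_fit = float(state.pbest_fit[best])
        state.gbest_pos = state.pbest_pos[best].copy()

    state.positions = x
    state.velocities = v
    state.trace.append(state.gbest_fit)
    return state


def pso_optimize(
    fitness, cfg: PsoConfig, x0: np.ndarray | None = None
) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the swarm for ``cfg.n_iters`` steps.

    Returns (gbest position, gbest fitness, trace). The trace holds the
    best-so-far fitness after initialization and after each iteration
    (length n_iters + 1) and is non-increasing by construction. ``x0``
    optionally seeds initial particles with known candidates.
    """
    rng = np.random.default_rng(cfg.seed)
    state = pso_init(fitness, cfg, rng, x0=x0)
    for _ in range(cfg.n_iters):
        pso_step(state, cfg, fitness, rng)
    return state.gbest_pos.copy(), state.gbest_fit, np.array(state.trace)
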