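"""Salp swarm algorithm (SSA) for bounded continuous minimization.

The swarm models a salp chain. The first individual (the leader) explores
globally around the best solution found so far (the "food" position F):

    x_1[i] = F[i] +/- c1 * ((Xmax[i] - Xmin[i]) * c2 + Xmin[i])

with c2, c3 ~ U[0,1] redrawn per dimension (c3 >= 0.5 selects +) and the
convergence factor

    c1 = 2 * exp(-(4 t / T)^2)

shrinking from 2 toward ~0 over the run, trading exploration for
exploitation. Followers track their predecessor: each follower moves to the
midpoint of its own and the preceding salp's position, applied sequentially
down the chain. Positions are clamped to the box after every move, and the
food position is best-so-far bookkeeping, so the reported fitness trace is
monotone non-increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, InputError, OptimizationError

__all__ = [
    "SSAConfig",
    "SSAResult",
    "init_population",
    "convergence_factor",
    "update_leader",
    "update_followers",
    "run_ssa",
]


@dataclass
class SSAConfig:
    """Swarm size m, dimension n, box bounds, iteration budget T, seed."""

    m: int
    n: int
    xmin: np.ndarray
    xmax: np.ndarray
    T: int
    seed: int | None = None

    def __post_init__(self) -> None:
        self.xmin = np.broadcast_to(np.asarray(self.xmin, float), (self.n,)).copy()
        self.xmax = np.broadcast_to(np.asarray(self.xmax, float), (self.n,)).copy()
        if self.m < 2:
            raise ConfigError("population size m must be >= 2")
        if self.T < 1:
            raise ConfigError("iteration budget T must be >= 1")
        if not np.all(self.xmin < self.xmax):
            raise ConfigError("bounds must satisfy xmin < xmax elementwise")


@dataclass
class SSAResult:
    best: np.ndarray
    best_fitness: float
    history: np.ndarray  # food fitness after each iteration, length T
    evaluations: int = 0
    positions: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))


def init_population(cfg: SSAConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform initialization: rand() * (Xmax - Xmin) + Xmin, i.i.d."""
    return rng.random((cfg.m, cfg.n)) * (cfg.xmax - cfg.xmin) + cfg.xmin


def convergence_factor(t: int, T: int) -> float:
    """c1 = 2 exp(-(4t/T)^2); 2 at t=0, ~2.25e-7 at t=T."""
    if T < 1:
        raise InputError("T must be >= 1")
    return 2.0 * float(np.exp(-((4.0 * t / T) ** 2)))


def update_leader(
    food: np.ndarray, cfg: SSAConfig, c1: float, rng: np.random.Generator
) -> np.ndarray:
    """New leader position around the food, clamped to the box."""
    c2 = rng.random(cfg.n)
    c3 = rng.random(cfg.n)
    step = c1 * ((cfg.xmax - cfg.xmin) * c2 + cfg.xmin)
    leader = np.where(c3 >= 0.5, food + step, food - step)
    return np.clip(leader, cfg.xmin, cfg.xmax)


def update_followers(positions: np.ndarray) -> np.ndarray:
    """Sequential chain update: row j moves to midpoint of rows j and j-1.

    Row j-1 has already moved when row j moves (in-place down the chain);
    the leader row is untouched.
    """
    out = positions.copy()
    for j in range(1, out.shape[0]):
        out[j] = (out[j] + out[j - 1]) / 2.0
    return out


def _evaluate(
    fitness_fn: Callable[[np.ndarray], float], positions: np.ndarray
) -> np.ndarray:
    values = np.empty(positions.shape[0])
    for i, row in enumerate(positions):
        v = float(fitness_fn(row))
        if not np.isfinite(v):
            raise OptimizationError(
                f"fitness function returned non-finite value {v} at {row!r}"
            )
        values[i] = v
    return values


def run_ssa(
    fitness_fn: Callable[[np.ndarray], float],
    cfg: SSAConfig,
    rng: np.random.Generator | None = None,
    initial_positions: Sequence[np.ndarray] | np.ndarray | None = None,
) -> SSAResult:
    """Minimize fitness_fn over the box; returns the food position and trace.

    ``initial_positions`` optionally seeds the first rows of the swarm
    (clamped to the box) — used to warm-start parameter polishing from an
    existing solution; remaining rows are drawn uniformly.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    positions = init_population(cfg, rng)
    if initial_positions is not None:
        seeds = np.atleast_2d(np.asarray(initial_positions, float))
        if seeds.shape[1] != cfg.n:
            raise InputError("seed positions have wrong dimension")
        k = min(seeds.shape[0], cfg.m)
        positions[:k] = np.clip(seeds[:k], cfg.xmin, cfg.xmax)

    fitness = _evaluate(fitness_fn, positions)
    best_idx = int(np.argmin(fitness))
    food = positions[best_idx].copy()
    food_fitness = float(fitness[best_idx])
    evaluations = cfg.m

    history = np.empty(cfg.T)
    for t in range(1, cfg.T + 1):
        c1 = convergence_factor(t, cfg.T)
        positions[0] = update_leader(food, cfg, c1, rng)
        positions = update_followers(positions)
        positions = np.clip(positions, cfg.xmin, cfg.xmax)
        fitness = _evaluate(fitness_fn, positions)
        evaluations += cfg.m
        best_idx = int(np.argmin(fitness))
        if fitness[best_idx] < food_fitness:
            food_fitness = float(fitness[best_idx])
            food = positions[best_idx].copy()
        history[t - 1] = food_fitness

    return SSAResult(
        best=food,
        best_fitness=food_fitness,
        history=history,
        evaluations=evaluations,
        positions=positions,
    )
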