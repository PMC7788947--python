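"""Flexible-weight discrete binary particle swarm optimisation (FEBPSO).

Particles are 48-bit strings, six bits per boosted-tree hyperparameter.
Velocities follow the classic update

    v' = w(k) v + c1 r1 (pbest - x) + c2 r2 (gbest - x)

clamped to [v_min, v_max], and each bit resamples to 1 with probability
sigmoid(v').  The inertia weight follows a flexible exponential schedule

    w(k) = a1 exp(-psi k / T) + a2 exp(psi k / T)

with a1, a2 chosen so that w(0) = w1 and w(T) = w2.  For psi > ln 2 the
schedule dips below w1 in the interior before rising to w2 — this is the
intended behaviour, trading early exploration against late exploitation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

BITS_PER_PARAM = 6
GRID = (1 << BITS_PER_PARAM) - 1  # 63


@dataclass(frozen=True)
class ParamSpec:
    name: str
    lo: float
    hi: float
    kind: str = "real"  # "real" | "integer"
    bits: int = BITS_PER_PARAM

    def decode(self, i: int) -> float | int:
        v = self.lo + (i / GRID) * (self.hi - self.lo)
        return int(round(v)) if self.kind == "integer" else v


@dataclass(frozen=True)
class HyperparamSpace:
    """Bounded 8-parameter boosted-tree search space, 48 bits total."""

    params: tuple = (
        ParamSpec("learning_rate", 0.01, 0.3),
        ParamSpec("gamma", 0.0, 2.0),
        ParamSpec("max_depth", 3, 10, kind="integer"),
        ParamSpec("min_child_weight", 1, 15, kind="integer"),
        ParamSpec("subsample", 0.1, 1.0),
        ParamSpec("colsample_bytree", 0.0, 1.0),
        ParamSpec("lambda", 0.01, 2.0),
        ParamSpec("iteration_times", 100, 6000, kind="integer"),
    )

    @property
    def n_bits(self) -> int:
        return sum(p.bits for p in self.params)

    def with_bounds(self, **bounds) -> "HyperparamSpace":
        """Return a copy with (lo, hi) overridden for the named parameters."""
        new = []
        for p in self.params:
            if p.name in bounds:
                lo, hi = bounds[p.name]
                p = replace(p, lo=float(lo), hi=float(hi))
            new.append(p)
        return HyperparamSpace(params=tuple(new))


@dataclass
class SwarmConfig:
    """Swarm hyperparameters; defaults follow the published configuration
    (25 particles, acceleration constants 1.5, inertia weight 0.4→0.8,
    psi=2.6, velocities clamped to ±10; T=50 for compound-series models,
    T=20 for shRNA-series)."""

    n_particles: int = 25
    T: int = 50
    c1: float = 1.5
    c2: float = 1.5
    w1: float = 0.4
    w2: float = 0.8
    psi: float = 2.6
    v_min: float = -10.0
    v_max: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.w1 <= self.w2:
            raise ValueError("require 0 < w1 <= w2")
        if self.psi == 0:
            raise ValueError("psi must be nonzero")
        if self.T < 1:
            raise ValueError("T must be >= 1")


@dataclass
class OptimResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # global-best fitness after each iteration (incl. init)
    best_params: dict | None = None
    n_nonfinite: int = 0


def flexible_weight(k: int, cfg: SwarmConfig) -> float:
    """Inertia weight at iteration ``k`` of the exponential schedule."""
    cfg.validate()
    e1 = math.exp(cfg.psi)
    e2 = math.exp(2.0 * cfg.psi)
    a1 = (cfg.w2 * e1 - cfg.w1 * e2) / (1.0 - e2)
    a2 = (cfg.w1 - cfg.w2 * e1) / (1.0 - e2)
    return a1 * math.exp(-cfg.psi * k / cfg.T) + a2 * math.exp(cfg.psi * k / cfg.T)


def update_velocity(
    velocity: np.ndarray,
    position: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    w: float,
    cfg: SwarmConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One velocity step; r1, r2 are fresh uniforms per component."""
    r1 = rng.random(velocity.shape)
    r2 = rng.random(velocity.shape)
    v = w * velocity + cfg.c1 * r1 * (pbest - position) + cfg.c2 * r2 * (gbest - position)
    return np.clip(v, cfg.v_min, cfg.v_max)


def update_position(velocity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample each bit to 1 with probability sigmoid(velocity)."""
    p = 1.0 / (1.0 + np.exp(-velocity))
    return (rng.random(velocity.shape) < p).astype(np.int8)


def decode(position, space: HyperparamSpace) -> dict:
    """Map a 48-bit position to named parameter values.

    Consecutive 6-bit groups are read most-significant-bit first, one per
    parameter in declared order; the integer i in [0, 63] maps linearly to
    lo + (i/63)(hi - lo), rounded for integer-kind parameters.
    """
    bits = np.asarray(position, dtype=int)
    if bits.size != space.n_bits:
        raise ValueError(f"position has {bits.size} bits, space needs {space.n_bits}")
    out = {}
    pos = 0
    for p in space.params:
        group = bits[pos: pos + p.bits]
        i = int("".join(map(str, group)), 2)
        out[p.name] = p.decode(i)
        pos += p.bits
    return out


def encode(values: dict, space: HyperparamSpace) -> np.ndarray:
    """Inverse of :func:`decode` on the 64-point per-parameter grid."""
    bits = []
    for p in space.params:
        v = values[p.name]
        i = int(round((v - p.lo) / (p.hi - p.lo) * GRID)) if p.hi > p.lo else 0
        i = min(max(i, 0), GRID)
        bits.extend(int(b) for b in format(i, f"0{p.bits}b"))
    return np.array(bits, dtype=np.int8)


def optimize(
    fitness,
    cfg: SwarmConfig,
    space: HyperparamSpace | None = None,
    n_bits: int | None = None,
) -> OptimResult:
    """Run the swarm and return the best position found.

    ``fitness`` maps a 0/1 position vector to a real score (higher is
    better); non-finite scores are treated as -inf and counted.  With a
    ``space`` the returned result also carries the decoded parameters.
    Reproducible under a fixed ``cfg.seed``.
    """
    cfg.validate()
    if n_bits is None:
        if space is None:
            raise ValueError("provide either a HyperparamSpace or n_bits")
        n_bits = space.n_bits
    rng = np.random.default_rng(cfg.seed)

    X = (rng.random((cfg.n_particles, n_bits)) < 0.5).astype(np.int8)
    V = rng.uniform(-1.0, 1.0, size=(cfg.n_particles, n_bits))

    def safe_fitness(x) -> float:
        f = fitness(x)
        if f is None or not np.isfinite(f):
            logger.warning("non-finite fitness: treating as -inf")
            return -math.inf, True
        return float(f), False

    n_nonfinite = 0
    fit = np.empty(cfg.n_particles)
    for i in range(cfg.n_particles):
        fit[i], bad = safe_fitness(X[i])
        n_nonfinite += bad
    pbest = X.copy()
    pbest_fit = fit.copy()
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
    history = [gbest_fit]

    for k in range(1, cfg.T + 1):
        w = flexible_weight(k, cfg)
        for i in range(cfg.n_particles):
            V[i] = update_velocity(V[i], X[i], pbest[i], gbest, w, cfg, rng)
            X[i] = update_position(V[i], rng)
            f, bad = safe_fitness(X[i])
            n_nonfinite += bad
            if f > pbest_fit[i]:
                pbest[i] = X[i].copy()
                pbest_fit[i] = f
                if f > gbest_fit:
                    gbest, gbest_fit = X[i].copy(), f
        history.append(gbest_fit)

    return OptimResult(
        best_position=gbest,
        best_fitness=gbest_fit,
        history=np.array(history),
        best_params=decode(gbest, space) if space is not None else None,
        n_nonfinite=n_nonfinite,
    )
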