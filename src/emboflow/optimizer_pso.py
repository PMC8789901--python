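"""Modified particle swarm optimization over the nonnegative control box.

Modifications relative to the plain inertia-weighted PSO:

* disjoint-subdomain initialization -- the box is sliced into M equal slabs
  along the first coordinate and one particle starts uniformly inside each;
* nonnegativity handling -- negative coordinates of a proposed position are
  set to zero and the velocity is recomputed as the realized displacement;
* probabilistic reinitialization -- after the best-position bookkeeping,
  each particle independently returns to a uniform point of its OWN
  original subdomain with probability P (velocity reset to zero), which
  keeps exploring the admissible region near the penalty boundary.

The inertia weight decays linearly, w^k = w1 - w2*k/I.  Personal bests are
replaced only when strictly better; the global best is the argmin of the
personal bests, so its value is non-increasing across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np


@dataclass
class SwarmConfig:
    """Swarm size, schedule and box geometry.

    ``bounds`` are per-coordinate upper limits b_l of the box [0, b_l]; the
    problem only requires nonnegativity, but the subdomain sampling needs a
    bounded region.  ``rand_per_coordinate`` selects whether the stochastic
    factors r1, r2 are drawn per coordinate (default, the common convention)
    or as per-particle scalars.
    """

    M: int = 16
    I: int = 300
    P: float = 0.15
    w1: float = 0.9
    w2: float = 0.5
    c1: float = 1.49
    c2: float = 1.49
    R: float = 1000.0
    bounds: Optional[np.ndarray] = None
    seed: int = 0
    rand_per_coordinate: bool = True

    def validate(self, dim: Optional[int] = None) -> None:
        if not 0.0 <= self.P <= 1.0:
            raise ValueError("P must lie in [0,1]")
        if not 0.0 < self.w2 < self.w1 < 1.0:
            raise ValueError("need 0 < w2 < w1 < 1")
        if self.M < 1 or self.I < 1:
            raise ValueError("M and I must be >= 1")
        if self.bounds is not None:
            b = np.asarray(self.bounds, float)
            if np.any(b <= 0):
                raise ValueError("all upper bounds must be positive")
            if dim is not None and b.shape != (dim,):
                raise ValueError("bounds dimension mismatch")


@dataclass
class SwarmState:
    x: np.ndarray          # (M, d) positions
    v: np.ndarray          # (M, d) velocities
    p: np.ndarray          # (M, d) personal bests
    p_value: np.ndarray    # (M,) personal-best objective values
    p_g: np.ndarray        # (d,) global best
    p_g_value: float
    k: int
    subdomains: List[Tuple[np.ndarray, np.ndarray]]  # (low, high) per particle


def init_subdomains(bounds: np.ndarray, M: int) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Slice the box [0,b_1]x...x[0,b_d] into M equal slabs along axis 0.

    Slabs are half-open in the first coordinate (the last one closed), so
    they are pairwise disjoint and their union is the whole box.
    """
    b = np.asarray(bounds, dtype=float)
    out = []
    for j in range(M):
        low = np.zeros_like(b)
        high = b.copy()
        low[0] = b[0] * j / M
        high[0] = b[0] * (j + 1) / M
        out.append((low, high))
    return out


def _sample(subdomain, rng: np.random.Generator) -> np.ndarray:
    low, high = subdomain
    return low + rng.random(low.size) * (high - low)


def init_swarm(config: SwarmConfig, subdomains, objective,
               rng: np.random.Generator) -> SwarmState:
    """One uniform point per subdomain, zero velocities, bests evaluated."""
    x = np.array([_sample(sd, rng) for sd in subdomains])
    v = np.zeros_like(x)
    p_value = np.array([float(objective(xi)) for xi in x])
    if not np.all(np.isfinite(p_value)):
        raise ValueError("objective returned a non-finite value")
    g = int(np.argmin(p_value))
    return SwarmState(x=x, v=v, p=x.copy(), p_value=p_value,
                      p_g=x[g].copy(), p_g_value=float(p_value[g]), k=0,
                      subdomains=subdomains)


def step(state: SwarmState, config: SwarmConfig, objective,
         rng: np.random.Generator) -> SwarmState:
    """One iteration: velocity/position update, clipping, bests, reinit."""
    M, d = state.x.shape
    w = config.w1 - config.w2 * state.k / config.I
    if config.rand_per_coordinate:
        r1 = rng.random((M, d))
        r2 = rng.random((M, d))
    else:
        r1 = rng.random((M, 1))
        r2 = rng.random((M, 1))
    v_bar = (w * state.v + config.c1 * r1 * (state.p - state.x)
             + config.c2 * r2 * (state.p_g[None, :] - state.x))
    x_bar = state.x + v_bar
    x_til = np.where(x_bar < 0.0, 0.0, x_bar)
    v_til = x_til - state.x

    values = np.array([float(objective(xi)) for xi in x_til])
    if not np.all(np.isfinite(values)):
        raise ValueError("objective returned a non-finite value")
    improve = values < state.p_value        # strict: ties keep the old best
    p = np.where(improve[:, None], x_til, state.p)
    p_value = np.where(improve, values, state.p_value)
    g = int(np.argmin(p_value))

    reinit = rng.random(M) < config.P
    x_new = x_til.copy()
    v_new = v_til.copy()
    for j in np.nonzero(reinit)[0]:
        x_new[j] = _sample(state.subdomains[j], rng)
        v_new[j] = 0.0

    return SwarmState(x=x_new, v=v_new, p=p, p_value=p_value,
                      p_g=p[g].copy(), p_g_value=float(p_value[g]),
                      k=state.k + 1, subdomains=state.subdomains)


def optimize(config: SwarmConfig,
             objective: Callable[[np.ndarray], float],
             rng: Optional[np.random.Generator] = None):
    """Full PSO run: init + I iterations.

    Returns (p_g, p_g_value, history) where history holds the best value
    after initialization and after each iteration (length I+1,
    non-increasing).
    """
    if config.bounds is None:
        raise ValueError("config.bounds must be set")
    b = np.asarray(config.bounds, dtype=float)
    config.validate(dim=b.size)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    subdomains = init_subdomains(b, config.M)
    state = init_swarm(config, subdomains, objective, rng)
    history = [state.p_g_value]
    for _ in range(config.I):
        state = step(state, config, objective, rng)
        history.append(state.p_g_value)
    return state.p_g.copy(), state.p_g_value, np.asarray(history)
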