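"""Per-stage trapezoid injection controls and optimizer-vector packing.

The embolic-agent inflow at stage ``i`` is q_e(t) = gamma_i * Q_i(T_{i-1})
* E_i(t), where E_i ramps linearly from 0 to 1 over ``theta1_i`` seconds,
holds the plateau for ``theta2_i`` seconds, and ramps back down over the
fixed terminal interval ``epsilon``.  When ``theta1_i`` collapses to zero
the profile becomes the discontinuous ("bang") variant: E jumps to 1
immediately after the stage start (E=0 at the start instant itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

#: Below this ramp-up duration (s) the continuous profile degenerates
#: numerically and the discontinuous variant is used instead.
THETA_SWITCH = 1e-8

#: Default terminal ramp-down (s); a fixed constant, not a control variable,
#: reflecting the clinical practice of quickly stopping the agent supply.
DEFAULT_EPSILON = 0.1


@dataclass
class StageControl:
    """One stage's control triple (gamma, theta1, theta2), all nonnegative."""

    gamma: float
    theta1: float
    theta2: float

    def __post_init__(self):
        if self.gamma < 0 or self.theta1 < 0 or self.theta2 < 0:
            raise ValueError("stage control parameters must be nonnegative")


@dataclass
class ControlPlan:
    """Ordered stages plus the fixed ramp-down duration epsilon (> 0)."""

    stages: List[StageControl]
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if len(self.stages) < 1:
            raise ValueError("a plan needs at least one stage")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def stage_duration(self, i: int) -> float:
        st = self.stages[i]
        return st.theta1 + st.theta2 + self.epsilon


def stage_times(plan: ControlPlan) -> List[float]:
    """Stage boundaries T_0 ... T_N with T_0 = 0, strictly increasing."""
    times = [0.0]
    for i in range(plan.n_stages):
        times.append(times[-1] + plan.stage_duration(i))
    return times


def ramp_profile(plan: ControlPlan, i: int, t: float) -> float:
    """Dimensionless injection envelope E_i(t) in [0,1] for t in [T_{i-1}, T_i].

    Piecewise-linear ramp/plateau/ramp-down; for theta1 below THETA_SWITCH
    the discontinuous variant applies (E=0 exactly at the stage start).
    """
    T = stage_times(plan)
    t0, t1 = T[i], T[i + 1]
    if not (t0 <= t <= t1 + 1e-12 * max(1.0, abs(t1))):
        raise ValueError(f"t={t} outside stage interval [{t0}, {t1}]")
    st = plan.stages[i]
    eps = plan.epsilon
    if st.theta1 <= THETA_SWITCH:
        if t == t0:
            return 0.0
        if t <= t1 - eps:
            return 1.0
        return max(0.0, (t1 - t) / eps)
    if t <= t0 + st.theta1:
        return (t - t0) / st.theta1
    if t <= t1 - eps:
        return 1.0
    return max(0.0, (t1 - t) / eps)


def embolic_flow(plan: ControlPlan, i: int, Q_start: float, t: float) -> float:
    """Embolic inflow q_e(t) = gamma_i * Q_start * E_i(t) (cm^3/s).

    ``Q_start`` is the mixture flow frozen at the stage start; since
    q_e(T_{i-1}) = 0 it equals the healthy-bed inflow at the stage-initial
    mean saturation.
    """
    return plan.stages[i].gamma * Q_start * ramp_profile(plan, i, t)


def pack(plan: ControlPlan) -> np.ndarray:
    """Flatten a plan to the optimizer vector (stage-major ordering).

    Ordering: (gamma_1, theta1_1, theta2_1, gamma_2, theta1_2, theta2_2, ...).
    """
    out = np.empty(3 * plan.n_stages)
    for i, st in enumerate(plan.stages):
        out[3 * i : 3 * i + 3] = (st.gamma, st.theta1, st.theta2)
    return out


def unpack(vector: Sequence[float], N: int, epsilon: float = DEFAULT_EPSILON) -> ControlPlan:
    """Inverse of :func:`pack`; validates length and nonnegativity."""
    v = np.asarray(vector, dtype=float)
    if v.shape != (3 * N,):
        raise ValueError(f"expected a vector of length {3 * N}, got shape {v.shape}")
    if np.any(v < 0):
        raise ValueError("control vector entries must be nonnegative")
    stages = [StageControl(*v[3 * i : 3 * i + 3]) for i in range(N)]
    return ControlPlan(stages=stages, epsilon=epsilon)
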