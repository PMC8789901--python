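"""Stage chaining, objective, safety constraints and the penalized functional.

Between stages the deposited agent solidifies: the lumen available to the
next stage shrinks nodewise to A_i = A_{i-1} * S_{i-1}(T_{i-1}).  Each stage
restarts from pure blood on the reduced lumen, so the fraction of the
ORIGINAL cross-section occupied by blood, Psi_i = S_i A_i / A_1, is
continuous across the break.  The operation quality is the spatial mean of
Psi_N at the end of the last stage (0 = fully embolized, 1 = untouched);
the two safety constraints per stage are (a) no agent reaches the venous
outlet (S_i(t, L) = 1) and (b) the inlet pressure never exceeds the
critical pressure p*.  Violations switch unit indicator penalties weighted
by R into the penalized functional used by the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .cabaret_solver import (A_FLOOR, Grid1D, SolveTrace, StageResult,
                             TOL_OUTLET, run_stage)
from .control import ControlPlan
from .model_core import FractionalFlow, PatientModel

DEFAULT_PENALTY = 1000.0


@dataclass
class PlanEvaluation:
    """Objective, penalties and traces of one simulated control plan."""

    J_N: float
    penalties: List[Tuple[int, int]]
    J_hat: float
    traces: List[SolveTrace]
    Psi_final: np.ndarray
    stage_results: Optional[List[StageResult]] = None


def link_stage(A_prev: np.ndarray, S_final: np.ndarray,
               A1: np.ndarray) -> np.ndarray:
    """Next-stage lumen A_i = A_{i-1} * S_{i-1}, floored at A_FLOOR * A1."""
    S_final = np.asarray(S_final, dtype=float)
    if np.any(S_final < 0) or np.any(S_final > 1):
        raise ValueError("terminal saturation must lie in [0,1] nodewise")
    return np.maximum(A_prev * S_final, A_FLOOR * np.asarray(A1, float))


def objective(Psi_final: np.ndarray, grid: Grid1D) -> float:
    """Midpoint-rule mean of Psi over the half-integer nodes: J_N in [0,1]."""
    return float(grid.h / grid.L * np.sum(Psi_final))


def check_constraints(trace: SolveTrace, model: PatientModel) -> Tuple[int, int]:
    """Safety indicators (I1, I2) from the recorded per-step values.

    I1 = 1 when the outlet saturation dips below 1 (agent enters the vein),
    I2 = 1 when the inlet pressure exceeds the critical pressure p*.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    I1 = int(np.min(trace.S_outlet) < 1.0 - TOL_OUTLET)
    I2 = int(np.max(trace.p1) > model.p_star)
    return I1, I2


def penalized_objective(J_N: float, penalties: List[Tuple[int, int]],
                        R: float = DEFAULT_PENALTY) -> float:
    """J_hat = J_N + R * sum_i (I1_i + I2_i)."""
    if R <= 0:
        raise ValueError("penalty weight R must be positive")
    return J_N + R * sum(i1 + i2 for i1, i2 in penalties)


def simulate_plan(model: PatientModel, ff: FractionalFlow, plan: ControlPlan,
                  grid: Grid1D, r: float = 0.5, R: float = DEFAULT_PENALTY,
                  use_fast: Optional[bool] = None,
                  keep_results: bool = False) -> PlanEvaluation:
    """Simulate all stages of a plan and aggregate objective and penalties.

    Stages run in order; each uses the lumen left by its predecessor and a
    control scale Q_i(T_{i-1}) = qbar_b(mean Psi at the stage start).
    Deterministic: identical inputs produce identical traces.

    ``use_fast`` selects the compiled kernel for parametric (synthetic)
    models; by default it is used whenever available and the model carries
    the parametric payload.  The numpy path is the reference implementation.
    """
    if use_fast is None:
        use_fast = model.bed is not None
    if use_fast:
        from . import _kernel
        if model.bed is None or ff.params is None or not _kernel.AVAILABLE:
            use_fast = False

    A1_int = model.area(grid.x_nodes)
    A1_half = model.area(grid.x_half)
    A_int, A_half = A1_int.copy(), A1_half.copy()

    traces: List[SolveTrace] = []
    penalties: List[Tuple[int, int]] = []
    results: List[StageResult] = []
    for i in range(plan.n_stages):
        Vbar0 = float(grid.h / grid.L * np.sum(A_half / A1_half))
        Q_start = float(model.qbar_b(min(max(Vbar0, 0.0), 1.0)))
        if use_fast:
            from . import _kernel
            res = _kernel.run_stage_fast(model, ff, plan, i, A_int, A_half,
                                         grid, r, Q_start)
        else:
            res = run_stage(model, ff, plan, i, A_int, A_half, grid, r,
                            Q_start=Q_start)
        traces.append(res.trace)
        penalties.append(check_constraints(res.trace, model))
        if keep_results:
            results.append(res)
        if i < plan.n_stages - 1:
            A_int = link_stage(res.fields.A_int, res.fields.u, A1_int)
            A_half = link_stage(res.fields.A_half, res.fields.U, A1_half)
        else:
            Psi_final = res.fields.U * res.fields.A_half / A1_half

    J_N = objective(Psi_final, grid)
    J_hat = penalized_objective(J_N, penalties, R)
    return PlanEvaluation(J_N=J_N, penalties=penalties, J_hat=J_hat,
                          traces=traces, Psi_final=Psi_final,
                          stage_results=results if keep_results else None)
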