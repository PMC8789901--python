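"""Monotone CABARET scheme for one embolization stage.

The scheme advances two staggered sets of unknowns on a uniform grid over
[0, L]: flux variables ``u_j`` at integer nodes x_j = j*h and conservative
variables ``U_{j+1/2}`` at half-integer nodes.  One time step consists of
seven sub-stages:

1. CFL time step from the maximal characteristic speed a = Q f'(S)/(m A).
2. Mixture flow Q^n = q_e(t^n) + qbar_b(Vbar^n) and the inlet pressure from
   the discrete Darcy quadrature.
3. Conservative half-step to U^{n+1/2}.
4. Numerical fluxes at the half layer: the inlet flux from the integral
   boundary condition, interior fluxes by extrapolation with a two-sided
   limiter and an additional monotonicity correction.
5. Mixture flow Q^{n+1/2} at the half layer.
6. Conservative full step to U^{n+1}.
7. Flux-variable update: inlet value through the inverse fractional flow,
   interior values by extrapolation limited by the neighbouring U^{n+1}.

The additional flux correction caps (floors) the limited flux by
f(u_{k-1}^n) + phi_{k-1}^n on locally nondecreasing (nonincreasing)
four-point flux sequences, with phi = A m (U_{k-1/2}-u_{k-1})/(r^n Q^n);
this is the discrete local maximum principle bound, tight with equality for
linear advection at Courant number 1, which preserves the scheme's exact
translation property there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional

import numpy as np
import pandas as pd

from .control import ControlPlan, THETA_SWITCH, embolic_flow, stage_times
from .model_core import FractionalFlow, MMHG, PatientModel, S_FLOOR

#: Relative floor applied to the stage cross-section (A_i >= A_FLOOR * A1)
#: so 1/(m A_i) stays finite in fully embolized cells.
A_FLOOR = 1e-6

#: Outlet-saturation tolerance for the vein-protection constraint.
TOL_OUTLET = 1e-6

DEFAULT_MAX_STEPS = 2_000_000


@dataclass
class Grid1D:
    """Uniform grid with J cells on [0, L]; h = L/J."""

    J: int
    L: float

    def __post_init__(self):
        if self.J < 2:
            raise ValueError("J must be >= 2")
        if self.L <= 0:
            raise ValueError("L must be positive")

    @property
    def h(self) -> float:
        return self.L / self.J

    @property
    def x_nodes(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.J + 1)

    @property
    def x_half(self) -> np.ndarray:
        return (np.arange(self.J) + 0.5) * self.h


@dataclass
class StageFields:
    """Flux/conservative saturations plus the stage cross-section samples."""

    u: np.ndarray        # length J+1, integer nodes
    U: np.ndarray        # length J,   half-integer nodes
    A_int: np.ndarray    # stage cross-section at integer nodes
    A_half: np.ndarray   # stage cross-section at half-integer nodes


@dataclass
class StepRecord:
    t: float
    tau: float
    Q: float
    p1: float
    Sbar: float
    S_outlet: float


@dataclass
class SolveTrace:
    """Per-step records of one stage; the substrate for the constraints."""

    t: np.ndarray
    tau: np.ndarray
    Q: np.ndarray
    p1: np.ndarray
    Sbar: np.ndarray
    S_outlet: np.ndarray

    @classmethod
    def from_records(cls, records: List[StepRecord]) -> "SolveTrace":
        return cls(
            t=np.array([r.t for r in records]),
            tau=np.array([r.tau for r in records]),
            Q=np.array([r.Q for r in records]),
            p1=np.array([r.p1 for r in records]),
            Sbar=np.array([r.Sbar for r in records]),
            S_outlet=np.array([r.S_outlet for r in records]),
        )

    @classmethod
    def from_arrays(cls, arr: np.ndarray) -> "SolveTrace":
        return cls(t=arr[:, 0], tau=arr[:, 1], Q=arr[:, 2], p1=arr[:, 3],
                   Sbar=arr[:, 4], S_outlet=arr[:, 5])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "tau": self.tau, "Q": self.Q, "p1": self.p1,
             "Sbar": self.Sbar, "S_outlet": self.S_outlet}
        )

    def __len__(self) -> int:
        return self.t.size


@dataclass
class StageResult:
    fields: StageFields
    trace: SolveTrace
    Q_start: float
    max_p1: float
    min_S_outlet: float


# ---------------------------------------------------------------------------
# sub-stage operations
# ---------------------------------------------------------------------------

def cfl_timestep(fields: StageFields, Q: float, ff: FractionalFlow,
                 model: PatientModel, r: float, grid: Grid1D) -> float:
    """Time step tau = r*h / max_j a(U_{j+1/2}), a = Q f'(S)/(m A_i).

    Raises when the maximal pointwise speed vanishes (f' identically zero on
    the current states -- a degenerate model for this formula).  The stage
    driver uses the strengthened bound of :func:`_speed_bound` instead, which
    also covers shocks emanating from the inlet.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError("CFL number r must lie in (0, 1]")
    if Q <= 0:
        raise ValueError("Q must be positive")
    m_half = model.porosity(grid.x_half)
    a = Q * np.asarray(ff.df(fields.U)) / (m_half * fields.A_half)
    amax = float(np.max(a))
    if amax <= 0.0:
        raise ValueError("maximal characteristic speed is zero (f' vanishes)")
    return r * grid.h / amax


def _speed_bound(ff: FractionalFlow, Q: float, mA_min: float,
                 s_lo: float, s_hi: float, n: int = 65) -> float:
    """Upper bound on all signal speeds for states within [s_lo, s_hi].

    Shock speeds are mean values of f' over the jump interval, so the grid
    maximum of f' over the state range bounds rarefactions and shocks alike.
    """
    s_lo = max(0.0, min(s_lo, s_hi))
    s_hi = min(1.0, max(s_lo, s_hi))
    if s_hi - s_lo < 1e-12:
        grid = np.array([s_lo, s_hi])
    else:
        grid = np.linspace(s_lo, s_hi, n)
    fmax = float(np.max(np.asarray(ff.df(grid))))
    return Q * fmax / mA_min


def mixture_flow(q_e: float, Vbar: float, model: PatientModel) -> float:
    """Q = q_e + qbar_b(Vbar); positive by the healthy-bed floor."""
    if not -1e-12 <= Vbar <= 1.0 + 1e-12:
        raise ValueError("Vbar must lie in [0,1]")
    Q = q_e + float(model.qbar_b(min(max(Vbar, 0.0), 1.0)))
    if Q <= 0:
        raise ValueError("mixture flow is nonpositive; qbar_b must be > 0")
    return Q


def psi_values(fields: StageFields, A1_half: np.ndarray, grid: Grid1D):
    """Half-node Psi = U * A_i / A1 and its midpoint-rule mean."""
    V = fields.U * fields.A_half / A1_half
    Vbar = float(grid.h / grid.L * np.sum(V))
    return V, Vbar


def discrete_pressure(fields: StageFields, Q: float, model: PatientModel,
                      ff: FractionalFlow, grid: Grid1D,
                      A1_half: Optional[np.ndarray] = None) -> float:
    """Inlet pressure p1 (mmHg) from the discrete Darcy quadrature.

    p1 = p2(Vbar) + (Q eta_b / K) * sum_j f(V_{j+1/2}) h / (A1 k_b(V_{j+1/2}))
    with V = U A_i / A1; the dyn/cm^2 Darcy term is converted to mmHg.
    The integrand f/k_b has a finite limit at V=0, evaluated with a floor.
    """
    if A1_half is None:
        A1_half = model.area(grid.x_half)
    V, Vbar = psi_values(fields, A1_half, grid)
    Vf = np.maximum(V, S_FLOOR)
    darcy = Q * model.eta_b / model.K * float(
        np.sum(np.asarray(ff.f(Vf)) * grid.h / (A1_half * model.k_b(Vf)))
    )
    return float(model.p2(Vbar)) + darcy / MMHG


def half_step(fields: StageFields, Q: float, tau: float, ff: FractionalFlow,
              mA_half: np.ndarray, h: float) -> np.ndarray:
    """Conservative half-step: U^{n+1/2} from the layer-n flux variables."""
    f_u = np.asarray(ff.f(fields.u))
    return fields.U - (0.5 * tau) * Q / mA_half * (f_u[1:] - f_u[:-1]) / h


def boundary_flux(q_e_at_tn: float, U_layer: np.ndarray, fields: StageFields,
                  model: PatientModel, A1_half: np.ndarray, grid: Grid1D):
    """Inlet numerical flux from the integral boundary condition.

    f0 = qbar_b(Vbar) / (q_e + qbar_b(Vbar)) with Vbar the midpoint-rule
    mean of Psi evaluated on ``U_layer``.  Note the inflow q_e enters at the
    layer-n time even when ``U_layer`` is the half-layer state, exactly as
    the discretization prescribes.
    """
    V = U_layer * fields.A_half / A1_half
    Vbar = float(grid.h / grid.L * np.sum(V))
    qb = float(model.qbar_b(min(max(Vbar, 0.0), 1.0)))
    f0 = qb / (q_e_at_tn + qb)
    return f0, Vbar


def interior_fluxes(fields: StageFields, U_half_layer: np.ndarray, Q: float,
                    tau: float, ff: FractionalFlow, mA_int: np.ndarray,
                    h: float) -> np.ndarray:
    """Numerical fluxes f_j^{n+1/2} for j = 1..J.

    Preliminary extrapolated values are limited two-sidedly by the layer-n
    fluxes at (j-1/2, j); where the layer-n four-point flux sequence is
    monotone the additional correction caps/floors by f(u_{k-1}) + phi_{k-1}
    (nondecreasing branch checked first; non-strict comparisons, so constant
    states satisfy both and are left untouched).  Applied for k >= 2 only --
    the k-3/2 stencil value must exist.
    """
    u, U = fields.u, fields.U
    J = U.size
    f_u = np.asarray(ff.f(u))          # layer-n fluxes at integer nodes
    f_U = np.asarray(ff.f(U))          # layer-n fluxes at half nodes

    ubar_next = 2.0 * U_half_layer - u[:-1]          # j = 1..J
    ubar_half = 0.5 * (u[1:] + ubar_next)
    fbar = np.asarray(ff.f(np.clip(ubar_half, 0.0, 1.0)))

    lo = np.minimum(f_U, f_u[1:])
    hi = np.maximum(f_U, f_u[1:])
    ftil = np.clip(fbar, lo, hi)

    # additional monotonicity correction, k = 2..J
    if J >= 2:
        k = np.arange(2, J + 1)
        s0 = f_U[k - 2]      # f_{k-3/2}^n
        s1 = f_u[k - 1]      # f_{k-1}^n
        s2 = f_U[k - 1]      # f_{k-1/2}^n
        s3 = f_u[k]          # f_k^n
        nondec = (s0 <= s1) & (s1 <= s2) & (s2 <= s3)
        noninc = (s0 >= s1) & (s1 >= s2) & (s2 >= s3) & ~nondec
        rn = tau / h
        phi = mA_int[k - 1] * (U[k - 1] - u[k - 1]) / (rn * Q)
        bound = s1 + phi
        sel = ftil[k - 1]
        sel = np.where(nondec, np.minimum(sel, bound), sel)
        sel = np.where(noninc, np.maximum(sel, bound), sel)
        ftil[k - 1] = sel
    return ftil


def full_step(fields: StageFields, f_half_full: np.ndarray, Q_half: float,
              tau: float, mA_half: np.ndarray, h: float) -> np.ndarray:
    """Conservative full step with the half-layer fluxes (length J+1)."""
    return fields.U - tau * Q_half / mA_half * np.diff(f_half_full) / h


def flux_variable_update(fields: StageFields, U_new: np.ndarray,
                         f_half_full: np.ndarray, f0_next: float,
                         ff: FractionalFlow) -> np.ndarray:
    """Flux variables at the new layer.

    u_0 through the inverse fractional flow of the full-layer inlet flux;
    interior values extrapolated from the half-layer fluxes and limited by
    the two neighbouring U^{n+1}; the outflow node limited by its single
    interior neighbour together with its own previous value.
    """
    u = fields.u
    J = U_new.size
    u_half = np.asarray(ff.finv(f_half_full[1:]))    # j = 1..J
    util = 2.0 * u_half - u[1:]
    unew = np.empty_like(u)
    unew[0] = float(ff.finv(f0_next))
    lo = np.minimum(U_new[:-1], U_new[1:])
    hi = np.maximum(U_new[:-1], U_new[1:])
    unew[1:J] = np.clip(util[: J - 1], lo, hi)
    lo_J = min(U_new[J - 1], u[J])
    hi_J = max(U_new[J - 1], u[J])
    unew[J] = min(max(util[J - 1], lo_J), hi_J)
    return np.clip(unew, 0.0, 1.0)


# ---------------------------------------------------------------------------
# stage driver (integral boundary condition)
# ---------------------------------------------------------------------------

def run_stage(model: PatientModel, ff: FractionalFlow, plan: ControlPlan,
              i: int, A_int: np.ndarray, A_half: np.ndarray, grid: Grid1D,
              r: float = 0.5, Q_start: Optional[float] = None,
              max_steps: int = DEFAULT_MAX_STEPS) -> StageResult:
    """Run the CABARET scheme over stage ``i`` of a control plan.

    The stage starts from pure blood on the reduced lumen (u = U = 1) and
    integrates until the local time reaches the stage duration exactly;
    time steps are clipped to land on the control breakpoints (end of the
    ramp-up, start of the ramp-down, stage end) so the constraint
    functionals sample every kink of the control.
    """
    h, L, J = grid.h, grid.L, grid.J
    A1_int = model.area(grid.x_nodes)
    A1_half = model.area(grid.x_half)
    m_int = model.porosity(grid.x_nodes)
    m_half = model.porosity(grid.x_half)
    A_int = np.maximum(A_int, A_FLOOR * A1_int)
    A_half = np.maximum(A_half, A_FLOOR * A1_half)
    mA_int = m_int * A_int
    mA_half = m_half * A_half
    mA_min = float(np.min(mA_half))

    fields = StageFields(u=np.ones(J + 1), U=np.ones(J),
                         A_int=A_int, A_half=A_half)

    T = stage_times(plan)
    t_global0 = T[i]
    st = plan.stages[i]
    D = plan.stage_duration(i)
    bps = sorted({st.theta1, st.theta1 + st.theta2, D})
    bps = [b for b in bps if b > 1e-14]

    def qe(t_local: float) -> float:
        tg = min(t_global0 + t_local, T[i + 1])
        return embolic_flow(plan, i, Q_start, tg)

    if Q_start is None:
        _, Vbar0 = psi_values(fields, A1_half, grid)
        Q_start = float(model.qbar_b(Vbar0))

    records: List[StepRecord] = []
    t = 0.0
    n = 0
    duration_ok = D > 0
    if not duration_ok:
        raise ValueError("stage duration must be positive")

    while t < D - 1e-12:
        if n >= max_steps:
            raise RuntimeError(f"stage {i}: step count exceeded {max_steps}")
        V, Vbar = psi_values(fields, A1_half, grid)
        qe_n = qe(t)
        Qn = mixture_flow(qe_n, Vbar, model)
        p1n = discrete_pressure(fields, Qn, model, ff, grid, A1_half)
        qb = Qn - qe_n

        # --- time step: strengthened CFL bound with inlet anticipation ---
        s_lo = min(float(fields.u.min()), float(fields.U.min()))
        s_hi = max(float(fields.u.max()), float(fields.U.max()))
        s_b = float(ff.finv(qb / (qe_n + qb)))
        a1 = _speed_bound(ff, Qn, mA_min, min(s_lo, s_b), s_hi)
        tau = r * h / a1 if a1 > 0 else np.inf
        nb = next(b for b in bps if b > t + 1e-12)
        clipped = tau >= nb - t
        if clipped:
            tau = nb - t
        # second pass: the inlet state the boundary condition will impose by
        # the end of this tentative step
        qe_a = qe(min(t + tau, D))
        Q_a = max(Qn, qe_a + qb)
        s_b2 = float(ff.finv(qb / (qe_a + qb)))
        if s_b2 < min(s_lo, s_b) - 1e-15:
            a2 = _speed_bound(ff, Q_a, mA_min, s_b2, s_hi)
            if a2 > 0 and r * h / a2 < tau:
                tau = r * h / a2
                clipped = False
        t_new = nb if clipped else t + tau
        tau = t_new - t

        records.append(StepRecord(t, tau, Qn, p1n, Vbar, float(fields.u[-1])))

        # --- seven sub-stages ---
        U_half = half_step(fields, Qn, tau, ff, mA_half, h)
        f0_half, Vbar_half = boundary_flux(qe_n, U_half, fields, model,
                                           A1_half, grid)
        f_int = interior_fluxes(fields, U_half, Qn, tau, ff, mA_int, h)
        f_half_full = np.concatenate(([f0_half], f_int))
        qe_half = qe(min(t + 0.5 * tau, D))
        Q_half = mixture_flow(qe_half, Vbar_half, model)
        U_new = np.clip(full_step(fields, f_half_full, Q_half, tau,
                                  mA_half, h), 0.0, 1.0)
        tmp = StageFields(u=fields.u, U=U_new, A_int=A_int, A_half=A_half)
        qe_next = qe(min(t_new, D))
        f0_next, _ = boundary_flux(qe_next, U_new, tmp, model, A1_half, grid)
        fields.u = flux_variable_update(fields, U_new, f_half_full, f0_next, ff)
        fields.U = U_new
        t = t_new
        n += 1

    V, Vbar = psi_values(fields, A1_half, grid)
    qe_n = qe(D)
    Qn = mixture_flow(qe_n, Vbar, model)
    p1n = discrete_pressure(fields, Qn, model, ff, grid, A1_half)
    last_tau = records[-1].tau if records else D
    records.append(StepRecord(D, last_tau, Qn, p1n, Vbar, float(fields.u[-1])))

    trace = SolveTrace.from_records(records)
    return StageResult(fields=fields, trace=trace, Q_start=Q_start,
                       max_p1=float(np.max(trace.p1)),
                       min_S_outlet=float(np.min(trace.S_outlet)))


# ---------------------------------------------------------------------------
# prescribed-boundary driver (verification runs)
# ---------------------------------------------------------------------------

def run_prescribed(grid: Grid1D, ff: FractionalFlow, Q: float,
                   inflow: Callable[[float], float], u0: np.ndarray,
                   U0: np.ndarray, r: float = 0.5,
                   m: float | np.ndarray = 1.0,
                   A: float | np.ndarray = 1.0,
                   n_steps: Optional[int] = None,
                   t_end: Optional[float] = None,
                   record_fields: bool = False,
                   inflow_half: Optional[Callable[[float], float]] = None,
                   max_steps: int = DEFAULT_MAX_STEPS):
    """Advance the scheme with a prescribed mixture flow and inlet value.

    The inlet saturation is ``inflow(t)`` (the boundary flux is its
    fractional flow) and Q, m, A are constants -- the configuration of the
    translation and Riemann verification problems.  ``inflow_half``
    optionally overrides the inlet saturation at half layers; exact
    translation of a profile through the inlet requires the half-layer
    value to be the staggered (node-average) representation of the
    injected profile, which a pointwise sample only matches to O(h^2).
    Returns the final fields and, optionally, the per-step field history.
    """
    h, J = grid.h, grid.J
    m, A = float(m), float(A)
    mA_half = np.full(J, m * A)
    mA_int = np.full(J + 1, m * A)
    A_half = np.full(J, A)
    A_int = np.full(J + 1, A)

    fields = StageFields(u=np.array(u0, dtype=float),
                         U=np.array(U0, dtype=float),
                         A_int=A_int, A_half=A_half)
    mA_min = float(np.min(mA_half))
    history = []
    t = 0.0
    n = 0
    while True:
        if n_steps is not None and n >= n_steps:
            break
        if t_end is not None and t >= t_end - 1e-13:
            break
        if n >= max_steps:
            raise RuntimeError("prescribed run exceeded the step cap")
        s_lo = min(float(fields.u.min()), float(fields.U.min()),
                   float(inflow(t)))
        s_hi = max(float(fields.u.max()), float(fields.U.max()),
                   float(inflow(t)))
        a = _speed_bound(ff, Q, mA_min, s_lo, s_hi)
        if a <= 0:
            raise ValueError("zero signal speed; nothing to advance")
        tau = r * h / a
        if t_end is not None and t + tau > t_end:
            tau = t_end - t

        U_half = half_step(fields, Q, tau, ff, mA_half, h)
        g_half = (inflow_half(t + 0.5 * tau) if inflow_half is not None
                  else inflow(t + 0.5 * tau))
        f0_half = float(ff.f(g_half))
        f_int = interior_fluxes(fields, U_half, Q, tau, ff, mA_int, h)
        f_half_full = np.concatenate(([f0_half], f_int))
        U_new = np.clip(full_step(fields, f_half_full, Q, tau, mA_half, h),
                        0.0, 1.0)
        g_next = float(inflow(t + tau))
        unew = flux_variable_update(fields, U_new, f_half_full,
                                    float(ff.f(g_next)), ff)
        unew[0] = g_next  # prescribed inlet value (exact, no inversion noise)
        fields.u = unew
        fields.U = U_new
        t += tau
        n += 1
        if record_fields:
            history.append((t, fields.u.copy(), fields.U.copy()))
    return fields, t, history
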