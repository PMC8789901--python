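"""Compiled stage loop for parametric (synthetic) patient models.

The reference implementation of the scheme lives in ``cabaret_solver``;
this module replays the same algorithm as a numba kernel specialized to
the parametric model family (power-law relative permeabilities, power/
affine bed-response curves, trapezoid controls) so that optimization-scale
runs -- hundreds of plan evaluations with tens of thousands of time steps
each -- complete in seconds.  A test pins the two paths together.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    AVAILABLE = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    AVAILABLE = False

    def njit(*a, **k):  # type: ignore
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]

from .cabaret_solver import (A_FLOOR, SolveTrace, StageFields, StageResult,
                             Grid1D)
from .control import THETA_SWITCH, stage_times
from .model_core import MMHG, S_FLOOR

INV_TOL = 1e-12


@njit(cache=True)
def _f(s, ab, ae, eb, ee):
    if s <= 0.0:
        return 0.0
    if s >= 1.0:
        return 1.0
    lb = s ** ab / eb
    le = (1.0 - s) ** ae / ee
    return lb / (lb + le)


@njit(cache=True)
def _df(s, ab, ae, eb, ee):
    if s < 0.0:
        s = 0.0
    if s > 1.0:
        s = 1.0
    lb = s ** ab / eb
    le = (1.0 - s) ** ae / ee
    if s <= 0.0:
        dlb = 1.0 / eb if ab == 1.0 else 0.0
    else:
        dlb = ab * s ** (ab - 1.0) / eb
    if s >= 1.0:
        dle = -1.0 / ee if ae == 1.0 else 0.0
    else:
        dle = -ae * (1.0 - s) ** (ae - 1.0) / ee
    denom = (lb + le) ** 2
    if denom <= 0.0:
        return 0.0
    return (dlb * le - lb * dle) / denom


@njit(cache=True)
def _finv(y, ab, ae, eb, ee):
    if y <= 0.0:
        return 0.0
    if y >= 1.0:
        return 1.0
    lo = 0.0
    hi = 1.0
    s = y
    for _ in range(200):
        r = _f(s, ab, ae, eb, ee) - y
        if r > 0.0:
            hi = s
        else:
            lo = s
        d = _df(s, ab, ae, eb, ee)
        if d > 0.0:
            s_new = s - r / d
        else:
            s_new = 0.5 * (lo + hi)
        if abs(r) <= INV_TOL and (d <= 0.0 or abs(s_new - s) <= 1e-13):
            return s
        if not (lo < s_new < hi):
            s_new = 0.5 * (lo + hi)
        s = s_new
    return s


@njit(cache=True)
def _qbar(sbar, q_base, q_floor, q_shape):
    if sbar < 0.0:
        sbar = 0.0
    if sbar > 1.0:
        sbar = 1.0
    return q_base * (q_floor + (1.0 - q_floor) * sbar ** q_shape)


@njit(cache=True)
def _envelope(t, theta1, theta2, eps):
    """Trapezoid injection envelope on local stage time [0, D]."""
    D = theta1 + theta2 + eps
    if t > D:
        t = D
    if theta1 <= THETA_SWITCH:
        if t <= 0.0:
            return 0.0
        if t <= D - eps:
            return 1.0
        e = (D - t) / eps
        return e if e > 0.0 else 0.0
    if t <= theta1:
        return t / theta1
    if t <= D - eps:
        return 1.0
    e = (D - t) / eps
    return e if e > 0.0 else 0.0


@njit(cache=True)
def _fmax_on(ab, ae, eb, ee, s_lo, s_hi):
    if s_lo < 0.0:
        s_lo = 0.0
    if s_hi > 1.0:
        s_hi = 1.0
    if s_hi < s_lo:
        s_hi = s_lo
    n = 65
    best = 0.0
    if s_hi - s_lo < 1e-12:
        a = _df(s_lo, ab, ae, eb, ee)
        b = _df(s_hi, ab, ae, eb, ee)
        return a if a > b else b
    for i in range(n):
        s = s_lo + (s_hi - s_lo) * i / (n - 1)
        d = _df(s, ab, ae, eb, ee)
        if d > best:
            best = d
    return best


@njit(cache=True)
def _stage_loop(u, U, A_int, A_half, A1_int, A1_half, m_int, m_half,
                h, L, K, eta_b, p2_base, p2_drop, q_base, q_floor, q_shape,
                ab, ae, eb, ee, alpha_b,
                gamma, theta1, theta2, eps, Q_start, r_cfl,
                bps, records, max_steps):
    J = U.shape[0]
    mA_int = m_int * A_int
    mA_half = m_half * A_half
    mA_min = mA_half[0]
    for j in range(1, J):
        if mA_half[j] < mA_min:
            mA_min = mA_half[j]

    D = theta1 + theta2 + eps
    t = 0.0
    n_rec = 0
    n = 0

    f_u = np.empty(J + 1)
    f_U = np.empty(J)
    U_half = np.empty(J)
    fh = np.empty(J + 1)   # half-layer fluxes, fh[0] = inlet
    U_new = np.empty(J)
    u_new = np.empty(J + 1)

    while t < D - 1e-12:
        if n >= max_steps:
            return -1, t
        # layer-n means and flow
        Vbar = 0.0
        for j in range(J):
            Vbar += U[j] * A_half[j] / A1_half[j]
        Vbar *= h / L
        if Vbar > 1.0:
            Vbar = 1.0
        qe_n = gamma * Q_start * _envelope(t, theta1, theta2, eps)
        qb = _qbar(Vbar, q_base, q_floor, q_shape)
        Qn = qe_n + qb
        # pressure quadrature
        darcy = 0.0
        for j in range(J):
            V = U[j] * A_half[j] / A1_half[j]
            if V < S_FLOOR:
                V = S_FLOOR
            darcy += _f(V, ab, ae, eb, ee) * h / (A1_half[j] * V ** alpha_b)
        p1 = (p2_base - p2_drop * (1.0 - Vbar)) + Qn * eta_b / K * darcy / MMHG

        # time step: strengthened CFL bound with inlet anticipation
        s_lo = u[0]
        s_hi = u[0]
        for j in range(J + 1):
            if u[j] < s_lo:
                s_lo = u[j]
            if u[j] > s_hi:
                s_hi = u[j]
        for j in range(J):
            if U[j] < s_lo:
                s_lo = U[j]
            if U[j] > s_hi:
                s_hi = U[j]
        s_b = _finv(qb / (qe_n + qb), ab, ae, eb, ee)
        lo1 = s_b if s_b < s_lo else s_lo
        a1 = Qn * _fmax_on(ab, ae, eb, ee, lo1, s_hi) / mA_min
        tau = r_cfl * h / a1 if a1 > 0.0 else 1e30
        nb = D
        for i in range(bps.shape[0]):
            if bps[i] > t + 1e-12:
                nb = bps[i]
                break
        clipped = tau >= nb - t
        if clipped:
            tau = nb - t
        t_probe = t + tau
        if t_probe > D:
            t_probe = D
        qe_a = gamma * Q_start * _envelope(t_probe, theta1, theta2, eps)
        Q_a = qe_a + qb
        if Q_a < Qn:
            Q_a = Qn
        s_b2 = _finv(qb / (qe_a + qb), ab, ae, eb, ee)
        if s_b2 < lo1 - 1e-15:
            a2 = Q_a * _fmax_on(ab, ae, eb, ee, s_b2, s_hi) / mA_min
            if a2 > 0.0 and r_cfl * h / a2 < tau:
                tau = r_cfl * h / a2
                clipped = False
        t_new = nb if clipped else t + tau
        tau = t_new - t

        records[n_rec, 0] = t
        records[n_rec, 1] = tau
        records[n_rec, 2] = Qn
        records[n_rec, 3] = p1
        records[n_rec, 4] = Vbar
        records[n_rec, 5] = u[J]
        n_rec += 1

        # --- sub-stage 3: conservative half step ---
        for j in range(J + 1):
            f_u[j] = _f(u[j], ab, ae, eb, ee)
        for j in range(J):
            f_U[j] = _f(U[j], ab, ae, eb, ee)
            U_half[j] = U[j] - 0.5 * tau * Qn / mA_half[j] * (f_u[j + 1] - f_u[j]) / h

        # --- sub-stage 4: fluxes at the half layer ---
        Vbar_h = 0.0
        for j in range(J):
            Vbar_h += U_half[j] * A_half[j] / A1_half[j]
        Vbar_h *= h / L
        if Vbar_h > 1.0:
            Vbar_h = 1.0
        if Vbar_h < 0.0:
            Vbar_h = 0.0
        qb_h = _qbar(Vbar_h, q_base, q_floor, q_shape)
        fh[0] = qb_h / (qe_n + qb_h)
        rn = tau / h
        for j in range(1, J + 1):
            ubar_next = 2.0 * U_half[j - 1] - u[j - 1]
            ubar_half = 0.5 * (u[j] + ubar_next)
            if ubar_half < 0.0:
                ubar_half = 0.0
            if ubar_half > 1.0:
                ubar_half = 1.0
            fb = _f(ubar_half, ab, ae, eb, ee)
            lo = f_U[j - 1] if f_U[j - 1] < f_u[j] else f_u[j]
            hi = f_U[j - 1] if f_U[j - 1] > f_u[j] else f_u[j]
            if fb < lo:
                fb = lo
            if fb > hi:
                fb = hi
            if j >= 2:
                s0 = f_U[j - 2]
                s1 = f_u[j - 1]
                s2 = f_U[j - 1]
                s3 = f_u[j]
                nondec = (s0 <= s1) and (s1 <= s2) and (s2 <= s3)
                noninc = (s0 >= s1) and (s1 >= s2) and (s2 >= s3)
                if nondec or noninc:
                    phi = mA_int[j - 1] * (U[j - 1] - u[j - 1]) / (rn * Qn)
                    bound = s1 + phi
                    if nondec:
                        if fb > bound:
                            fb = bound
                    elif fb < bound:
                        fb = bound
            fh[j] = fb

        # --- sub-stages 5-6: half-layer flow, conservative full step ---
        qe_h = gamma * Q_start * _envelope(t + 0.5 * tau, theta1, theta2, eps)
        Q_half = qe_h + qb_h
        for j in range(J):
            val = U[j] - tau * Q_half / mA_half[j] * (fh[j + 1] - fh[j]) / h
            if val < 0.0:
                val = 0.0
            if val > 1.0:
                val = 1.0
            U_new[j] = val

        # --- sub-stage 7: flux variables ---
        Vbar_n = 0.0
        for j in range(J):
            Vbar_n += U_new[j] * A_half[j] / A1_half[j]
        Vbar_n *= h / L
        if Vbar_n > 1.0:
            Vbar_n = 1.0
        if Vbar_n < 0.0:
            Vbar_n = 0.0
        qb_n = _qbar(Vbar_n, q_base, q_floor, q_shape)
        qe_next = gamma * Q_start * _envelope(t_new, theta1, theta2, eps)
        u_new[0] = _finv(qb_n / (qe_next + qb_n), ab, ae, eb, ee)
        for j in range(1, J + 1):
            uh = _finv(fh[j], ab, ae, eb, ee)
            util = 2.0 * uh - u[j]
            if j < J:
                lo = U_new[j - 1] if U_new[j - 1] < U_new[j] else U_new[j]
                hi = U_new[j - 1] if U_new[j - 1] > U_new[j] else U_new[j]
            else:
                lo = U_new[J - 1] if U_new[J - 1] < u[J] else u[J]
                hi = U_new[J - 1] if U_new[J - 1] > u[J] else u[J]
            if util < lo:
                util = lo
            if util > hi:
                util = hi
            if util < 0.0:
                util = 0.0
            if util > 1.0:
                util = 1.0
            u_new[j] = util

        for j in range(J + 1):
            u[j] = u_new[j]
        for j in range(J):
            U[j] = U_new[j]
        t = t_new
        n += 1

    # terminal record
    Vbar = 0.0
    for j in range(J):
        Vbar += U[j] * A_half[j] / A1_half[j]
    Vbar *= h / L
    if Vbar > 1.0:
        Vbar = 1.0
    qe_n = gamma * Q_start * _envelope(D, theta1, theta2, eps)
    qb = _qbar(Vbar, q_base, q_floor, q_shape)
    Qn = qe_n + qb
    darcy = 0.0
    for j in range(J):
        V = U[j] * A_half[j] / A1_half[j]
        if V < S_FLOOR:
            V = S_FLOOR
        darcy += _f(V, ab, ae, eb, ee) * h / (A1_half[j] * V ** alpha_b)
    p1 = (p2_base - p2_drop * (1.0 - Vbar)) + Qn * eta_b / K * darcy / MMHG
    records[n_rec, 0] = D
    records[n_rec, 1] = records[n_rec - 1, 1] if n_rec > 0 else D
    records[n_rec, 2] = Qn
    records[n_rec, 3] = p1
    records[n_rec, 4] = Vbar
    records[n_rec, 5] = u[J]
    n_rec += 1
    return n_rec, t


def run_stage_fast(model, ff, plan, i, A_int, A_half, grid: Grid1D,
                   r: float, Q_start: float,
                   max_steps: int = 400_000) -> StageResult:
    """Wrapper dispatching one stage to the compiled loop."""
    bed = model.bed
    ab, ae, eb, ee = ff.params
    st = plan.stages[i]
    h, L, J = grid.h, grid.L, grid.J
    A1_int = model.area(grid.x_nodes)
    A1_half = model.area(grid.x_half)
    m_int = model.porosity(grid.x_nodes)
    m_half = model.porosity(grid.x_half)
    A_int = np.maximum(np.asarray(A_int, float), A_FLOOR * A1_int)
    A_half = np.maximum(np.asarray(A_half, float), A_FLOOR * A1_half)

    D = plan.stage_duration(i)
    bps = sorted({st.theta1, st.theta1 + st.theta2, D})
    bps = np.array([b for b in bps if b > 1e-14])

    u = np.ones(J + 1)
    U = np.ones(J)
    records = np.empty((max_steps + 2, 6))
    n_rec, t = _stage_loop(
        u, U, A_int, A_half, A1_int, A1_half, m_int, m_half,
        h, L, model.K, model.eta_b, bed.p_out_base, bed.p_out_drop,
        bed.q_base, bed.q_floor_frac, bed.q_shape,
        ab, ae, eb, ee, model.alpha_b,
        st.gamma, st.theta1, st.theta2, plan.epsilon, Q_start, r,
        bps, records, max_steps,
    )
    if n_rec < 0:
        raise RuntimeError(f"stage {i}: step count exceeded {max_steps}")
    trace = SolveTrace.from_arrays(records[:n_rec].copy())
    fields = StageFields(u=u, U=U, A_int=A_int, A_half=A_half)
    return StageResult(fields=fields, trace=trace, Q_start=Q_start,
                       max_p1=float(np.max(trace.p1)),
                       min_S_outlet=float(np.min(trace.S_outlet)))
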