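"""Physical model of the AVM: fractional flow, resistances, response curves.

The arteriovenous malformation (AVM) is treated as a one-dimensional porous
body of length ``L`` through which blood (the displaced phase, saturation
``S``) and an embolic agent (the displacing phase, saturation ``1 - S``)
filter jointly under Darcy's law.  The healthy vascular bed surrounding the
AVM is represented by two scalar response curves of the mean blood
saturation: the blood inflow ``qbar_b(Sbar)`` (strictly positive, so the
total mixture flow never vanishes and all characteristics run from the
arterial inlet to the venous outlet) and the outlet pressure ``p2(Sbar)``.

Units are CGS (cm, cm^2, cm^3/s, poise) except pressures, which stay in
clinical mmHg; the conversion 1 mmHg = 1333.22 dyn/cm^2 is applied inside
the pressure quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

#: 1 mmHg expressed in dyn/cm^2.
MMHG = 1333.22

#: 1 centipoise in poise.
CP = 0.01

#: Saturation floor used when evaluating f(S)/k_b(S) in the pressure
#: quadrature; the ratio has a finite limit at S=0 but 0/0 must be avoided.
S_FLOOR = 1e-12


@dataclass
class BedCurveParams:
    """Parameters of the synthetic healthy-bed response curves.

    q_base : blood inflow at Sbar=1 (cm^3/s), i.e. the pre-operative flow.
    q_floor_frac : fraction of q_base still entering at Sbar=0; keeping it
        positive guarantees Q(t) > 0 for any admissible control.
    q_shape : curvature exponent (>= 1) of the inflow curve.
    p_out_base : outlet pressure at Sbar=1 (mmHg).
    p_out_drop : outlet pressure change from Sbar=1 to Sbar=0 (mmHg).
    """

    q_base: float = 1.0
    q_floor_frac: float = 0.2
    q_shape: float = 2.0
    p_out_base: float = 30.0
    p_out_drop: float = 5.0

    def validate(self) -> None:
        if self.q_base <= 0:
            raise ValueError("q_base must be positive")
        if not 0.0 < self.q_floor_frac < 1.0:
            raise ValueError("q_floor_frac must lie in (0,1)")
        if self.q_shape < 1.0:
            raise ValueError("q_shape must be >= 1")


@dataclass
class PatientModel:
    """Geometry, filtration characteristics and bed response of one AVM.

    ``A1`` and ``m`` may be scalars (constant along the AVM) or callables of
    the position ``x`` in [0, L]; they are sampled at integer and
    half-integer grid nodes by the solver.
    """

    L: float
    A1: float | Callable[[np.ndarray], np.ndarray]
    m: float | Callable[[np.ndarray], np.ndarray]
    K: float
    alpha_b: float
    eta_b: float
    eta_e: float
    p_star: float
    qbar_b: Callable[[float], float]
    p2: Callable[[float], float]
    #: Parametric payload when the model comes from the synthetic generator;
    #: enables the compiled fast path.  None for free-form callables.
    bed: Optional[BedCurveParams] = None
    alpha_e: float = 2.0
    name: str = "custom"

    # -- sampling helpers -------------------------------------------------
    def area(self, x: np.ndarray) -> np.ndarray:
        """Initial cross-section A1 sampled at positions ``x`` (cm^2)."""
        x = np.asarray(x, dtype=float)
        if callable(self.A1):
            return np.asarray(self.A1(x), dtype=float) * np.ones_like(x)
        return float(self.A1) * np.ones_like(x)

    def porosity(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if callable(self.m):
            return np.asarray(self.m(x), dtype=float) * np.ones_like(x)
        return float(self.m) * np.ones_like(x)

    def k_b(self, S):
        """Blood relative permeability k_b(S) = S**alpha_b."""
        return np.power(np.clip(S, 0.0, 1.0), self.alpha_b)

    def validate(self) -> None:
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.K <= 0:
            raise ValueError("K must be positive")
        xs = np.linspace(0.0, self.L, 33)
        if np.any(self.area(xs) <= 0):
            raise ValueError("A1(x) must be positive on [0,L]")
        mvals = self.porosity(xs)
        if np.any(mvals <= 0) or np.any(mvals > 1):
            raise ValueError("m(x) must lie in (0,1]")
        sb = np.linspace(0.0, 1.0, 33)
        if min(float(self.qbar_b(s)) for s in sb) <= 0:
            raise ValueError("qbar_b must be strictly positive on [0,1]")
        if self.alpha_b <= 0:
            raise ValueError("alpha_b must be positive")


@dataclass
class FractionalFlow:
    """Buckley-Leverett fractional flow ``f`` with derivative and inverse.

    ``f`` maps [0,1] onto [0,1], is strictly increasing, and for the
    mobility-ratio construction is S-shaped with a single inflection ``xi``.
    ``finv`` is a safeguarded-bracketing inverse accurate to |f(S)-y|<=1e-12.
    """

    f: Callable[[np.ndarray], np.ndarray]
    df: Callable[[np.ndarray], np.ndarray]
    finv: Callable[[np.ndarray], np.ndarray] = field(default=None)  # type: ignore[assignment]
    xi: Optional[float] = None
    #: Parametric payload (alpha_b, alpha_e, eta_b, eta_e) when available.
    params: Optional[tuple] = None

    def __post_init__(self):
        if self.finv is None:
            self.finv = _make_inverse(self.f, self.df)


INV_TOL = 1e-12


def _invert_scalar(f, df, y: float) -> float:
    """Invert a strictly increasing f on [0,1]: Newton safeguarded by bisection.

    The bracket [lo, hi] always contains the root; Newton steps falling
    outside it are replaced by bisection.  Terminates on |f(S)-y| <= 1e-12.
    """
    if y <= 0.0:
        if y < -INV_TOL:
            raise ValueError(f"value {y} outside [0,1]")
        return 0.0
    if y >= 1.0:
        if y > 1.0 + INV_TOL:
            raise ValueError(f"value {y} outside [0,1]")
        return 1.0
    lo, hi = 0.0, 1.0
    s = y  # monotone f on [0,1]: the identity is a serviceable start
    for _ in range(200):
        fs = float(f(s))
        r = fs - y
        if r > 0.0:
            hi = s
        else:
            lo = s
        d = float(df(s))
        if d > 0.0:
            s_new = s - r / d
        else:
            s_new = 0.5 * (lo + hi)
        if abs(r) <= INV_TOL and (d <= 0.0 or abs(s_new - s) <= 1e-13):
            return s
        if not lo < s_new < hi:
            s_new = 0.5 * (lo + hi)
        s = s_new
    return s


def _invert_array(f, df, y: np.ndarray) -> np.ndarray:
    """Vectorized Newton iteration safeguarded by bisection on [0,1]."""
    y = np.asarray(y, dtype=float)
    if np.any(y < -INV_TOL) or np.any(y > 1.0 + INV_TOL):
        raise ValueError("values outside [0,1]")
    y = np.clip(y, 0.0, 1.0)
    lo = np.zeros_like(y)
    hi = np.ones_like(y)
    s = y.copy()
    for _ in range(120):
        r = np.asarray(f(s)) - y
        hi = np.where(r > 0, s, hi)
        lo = np.where(r <= 0, s, lo)
        d = np.asarray(df(s))
        newton = s - r / np.where(d > 0, d, 1.0)
        # converged when the residual meets the tolerance AND the Newton
        # step is negligible (the residual alone is a weak criterion where
        # f' vanishes at the endpoints)
        done = (np.abs(r) <= INV_TOL) & ((np.abs(newton - s) <= 1e-13) | (d <= 0))
        if done.all():
            break
        bad = (d <= 0) | (newton <= lo) | (newton >= hi)
        s = np.where(done, s, np.where(bad, 0.5 * (lo + hi), newton))
    s = np.where(y <= 0.0, 0.0, np.where(y >= 1.0, 1.0, s))
    return s


def _make_inverse(f, df):
    def finv(y):
        if np.ndim(y) == 0:
            return _invert_scalar(f, df, float(y))
        return _invert_array(f, df, y)

    return finv


def _locate_inflection(f, n: int = 4001) -> Optional[float]:
    """Single sign change of the second difference of f, if present."""
    s = np.linspace(0.0, 1.0, n)
    fs = np.asarray(f(s), dtype=float)
    d2 = np.diff(fs, 2)
    sign = np.sign(d2)
    sign[sign == 0] = 1
    changes = np.nonzero(np.diff(sign) != 0)[0]
    if changes.size == 0:
        return None
    k = int(changes[0])
    return float(s[k + 1])


def build_fractional_flow(model: PatientModel, alpha_e: Optional[float] = None) -> FractionalFlow:
    """Mobility-ratio fractional flow for a patient model.

    f(S) = [k_b(S)/eta_b] / [k_b(S)/eta_b + k_e(1-S)/eta_e] with
    k_b(S) = S**alpha_b and k_e(x) = x**alpha_e.  With real viscosities
    (blood 4 cP, agent 18 cP) and exponents > 1 this f is S-shaped:
    f(0)=0, f(1)=1, f'>0 on (0,1), convex below the inflection and concave
    above it.
    """
    if alpha_e is None:
        alpha_e = model.alpha_e
    if alpha_e < 1:
        raise ValueError("alpha_e must be >= 1")
    model.validate()
    ab, ae = float(model.alpha_b), float(alpha_e)
    eb, ee = float(model.eta_b), float(model.eta_e)

    def f(S):
        S = np.clip(S, 0.0, 1.0)
        lb = np.power(S, ab) / eb
        le = np.power(1.0 - S, ae) / ee
        return lb / (lb + le)

    def df(S):
        S = np.clip(S, 0.0, 1.0)
        lb = np.power(S, ab) / eb
        le = np.power(1.0 - S, ae) / ee
        dlb = ab * np.power(S, ab - 1.0) / eb if ab != 1.0 else np.full_like(np.asarray(S, float), 1.0 / eb)
        dle = -ae * np.power(1.0 - S, ae - 1.0) / ee if ae != 1.0 else np.full_like(np.asarray(S, float), -1.0 / ee)
        denom = (lb + le) ** 2
        return (dlb * le - lb * dle) / denom

    s = np.linspace(0.0, 1.0, 2001)
    fs = np.asarray(f(s))
    if np.any(np.diff(fs) <= 0):
        raise ValueError("fractional flow is not strictly increasing on [0,1]")
    return FractionalFlow(f=f, df=df, xi=_locate_inflection(f), params=(ab, ae, eb, ee))


def fractional_flow_invert(ff: FractionalFlow, y: float) -> float:
    """Saturation S in [0,1] with |f(S) - y| <= 1e-12 (f strictly increasing)."""
    return float(ff.finv(y))


def blood_resistance(model: PatientModel, x: float, S: float) -> float:
    """Local resistance to blood flow r_b = eta_b / (A(x) K k_b(S)).

    Diverges as S -> 0; callers integrating f(S) r_b guard via the finite
    f/k_b limit.  Raises on nonpositive saturation.
    """
    if S <= 0:
        raise ValueError("blood_resistance requires S > 0")
    A = float(model.area(np.asarray([x]))[0])
    return float(model.eta_b / (A * model.K * model.k_b(S)))


def validate_bl_shape(ff: FractionalFlow, n: int = 2001) -> dict:
    """Check the Buckley-Leverett shape conditions on a dense grid.

    Returns a pass/fail report per condition.  Failures are warnings, not
    errors: linear test fluxes (f(S)=S) remain usable by the solver.
    """
    s = np.linspace(0.0, 1.0, n)
    fs = np.asarray(ff.f(s), dtype=float)
    report = {
        "f0_zero": bool(abs(fs[0]) <= 1e-12),
        "f1_one": bool(abs(fs[-1] - 1.0) <= 1e-12),
        "strictly_increasing": bool(np.all(np.diff(fs) > 0)),
    }
    d2 = np.diff(fs, 2)
    sign = np.sign(d2)
    sign[np.abs(d2) < 1e-14] = 0
    nz = sign[sign != 0]
    single_switch = (
        nz.size > 0
        and nz[0] > 0
        and nz[-1] < 0
        and int(np.count_nonzero(np.diff(nz) != 0)) == 1
    )
    report["single_inflection"] = bool(single_switch)
    report["ok"] = all(report.values())
    return report
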