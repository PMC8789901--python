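"""Analytic self-similar solution of the pure-displacement Riemann problem.

For the scalar conservation law S_t + v f(S)_x = 0 with an S-shaped flux
(convex below the inflection, concave above), initial state S = 1 and inlet
state S = 0, the entropy solution is a rarefaction fan from 0 up to the
Welge tangent point S* followed by a tangential shock from S* to 1:

    f'(S*) (1 - S*) = 1 - f(S*),        S* in (0, xi),

with shock speed sigma = v f'(S*) (Rankine-Hugoniot slope of the chord to
(1, 1)).  Used as an independent oracle for the finite-difference scheme;
it never calls the scheme.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq

from .model_core import FractionalFlow


def welge_tangent_point(ff: FractionalFlow) -> float:
    """Tangent point S* of the chord from (1,1): f'(S*)(1-S*) = 1-f(S*)."""
    if ff.xi is None:
        raise ValueError("flux has no inflection; the tangent construction "
                         "needs an S-shaped f")

    def g(s):
        return float(ff.df(s)) * (1.0 - s) - (1.0 - float(ff.f(s)))

    lo, hi = 1e-10, ff.xi
    if g(hi) < 0:  # numeric inflection slightly early; extend the bracket
        hi = 1.0 - 1e-10
    return float(brentq(g, lo, hi, xtol=1e-14))


def shock_speed(ff: FractionalFlow, v: float = 1.0) -> float:
    """Shock speed sigma = v f'(S*) = v (1 - f(S*)) / (1 - S*)."""
    s_star = welge_tangent_point(ff)
    return v * float(ff.df(s_star))


def profile(x: np.ndarray, t: float, ff: FractionalFlow,
            v: float = 1.0) -> np.ndarray:
    """Saturation S(x, t): rarefaction fan then the pre-shock state 1.

    The fan inverts f' on [0, S*] (f' is increasing there, f being convex
    below the inflection); beyond the shock position x = v f'(S*) t the
    state is the undisturbed S = 1.
    """
    x = np.asarray(x, dtype=float)
    if t <= 0:
        return np.ones_like(x)
    s_star = welge_tangent_point(ff)
    sigma = v * float(ff.df(s_star))
    zeta = x / (v * t)
    out = np.ones_like(x)
    fan = zeta < sigma * (1.0 / v)  # zeta compared with f'(S*)
    dfp = lambda s: float(ff.df(s))
    for idx in np.nonzero(fan)[0]:
        z = zeta[idx]
        if z <= dfp(0.0):
            out[idx] = 0.0
        else:
            out[idx] = brentq(lambda s, zz=z: dfp(s) - zz, 0.0, s_star,
                              xtol=1e-13)
    return out


def shock_position(t: float, ff: FractionalFlow, v: float = 1.0) -> float:
    """Analytic shock location x_s(t) = v f'(S*) t."""
    return shock_speed(ff, v) * t
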