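"""Synthetic patient models: clinical geometries plus stand-in bed curves.

Geometrical and filtration characteristics of three reconstructed AVMs
(fixtures K, S and P: length, mean cross-section, absolute permeability,
blood relative-permeability exponent, critical pressure) are combined with
synthetic healthy-bed response curves.  The true response curves are
patient-specific interpolants of intraoperative measurements and are not
reproduced here; the stand-ins keep their qualitative shape -- the blood
inflow qbar_b(Sbar) is smooth, strictly increasing and strictly positive
(blood reroutes to the healthy bed as the AVM fills, but never fully), and
the outlet pressure p2(Sbar) is smooth and bounded:

    qbar_b(Sbar) = q_base * (q_floor + (1 - q_floor) * Sbar**q_shape)
    p2(Sbar)     = p_out_base - p_out_drop * (1 - Sbar)

Viscosities default to blood 4 cP and ONYX18 embolic agent 18 cP; porosity
m = 1 (other constant values rescale time) and the cross-section is the
constant pre-operative mean.
"""

from __future__ import annotations

from typing import Callable, Dict, Optional, Tuple

import numpy as np

from .model_core import MMHG, BedCurveParams, CP, PatientModel

#: Clinical geometry/filtration table: L (cm), A (cm^2), K (cm^2),
#: alpha_b (k_b = S**alpha_b), p* (mmHg).
FIXTURES: Dict[str, Tuple[float, float, float, float, float]] = {
    "K": (2.4, 2.275, 7.35e-7, 1.178, 80.7),
    "S": (3.0, 1.327, 8.35e-6, 1.380, 114.6),
    "P": (4.5, 4.714, 7.94e-6, 1.168, 55.0),
}

ETA_B = 4 * CP   # blood viscosity, poise
ETA_E = 18 * CP  # ONYX18 embolic agent viscosity, poise


def make_bed_curves(params: BedCurveParams) -> Tuple[Callable, Callable]:
    """Build (qbar_b, p2) response functions from bed-curve parameters."""
    params.validate()
    qb, floor, shape = params.q_base, params.q_floor_frac, params.q_shape
    pb, pd_ = params.p_out_base, params.p_out_drop

    def qbar_b(sbar):
        return qb * (floor + (1.0 - floor) * np.power(sbar, shape))

    def p2(sbar):
        return pb - pd_ * (1.0 - sbar)

    return qbar_b, p2


def patient_fixture(name: str, bed: Optional[BedCurveParams] = None) -> PatientModel:
    """Clinical-geometry fixture combined with synthetic bed curves."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    if bed is None:
        bed = BedCurveParams()
    L, A, K, alpha_b, p_star = FIXTURES[name]
    qbar_b, p2 = make_bed_curves(bed)
    model = PatientModel(L=L, A1=A, m=1.0, K=K, alpha_b=alpha_b,
                         eta_b=ETA_B, eta_e=ETA_E, p_star=p_star,
                         qbar_b=qbar_b, p2=p2, bed=bed, name=name)
    model.validate()
    return model


def random_patient(seed: int, ranges: Optional[dict] = None,
                   variable_fields: bool = False) -> PatientModel:
    """Random but valid patient model bracketing the clinical magnitudes.

    Deterministic given ``seed``.  With ``variable_fields`` the
    cross-section and porosity vary smoothly along the AVM (the solver
    supports nonconstant A(x) and m(x)); the parametric fast path then does
    not apply and the model uses the reference solver.
    """
    rng = np.random.default_rng(seed)
    rg = {
        "L": (2.0, 5.0), "A": (1.0, 5.0), "K": (5e-7, 1e-5),
        "alpha_b": (1.1, 1.4), "p_star": (50.0, 120.0),
        "q_base": (0.5, 2.0), "q_floor_frac": (0.1, 0.4),
        "q_shape": (1.0, 3.0),
    }
    if ranges:
        rg.update(ranges)

    def draw(key):
        lo, hi = rg[key]
        return float(lo + rng.random() * (hi - lo))

    L, A, K = draw("L"), draw("A"), draw("K")
    alpha_b, p_star = draw("alpha_b"), draw("p_star")
    bed = BedCurveParams(
        q_base=draw("q_base"), q_floor_frac=draw("q_floor_frac"),
        q_shape=draw("q_shape"),
        p_out_base=float(0.3 * p_star + 0.2 * p_star * rng.random()),
        p_out_drop=float(2.0 + 6.0 * rng.random()),
    )
    # keep the no-injection state feasible: baseline Darcy drop + outlet
    # pressure safely below p*
    darcy0 = bed.q_base * ETA_B * L / (K * A) / MMHG
    if bed.p_out_base + darcy0 > 0.9 * p_star:
        K = bed.q_base * ETA_B * L / (A * MMHG * (0.9 * p_star - bed.p_out_base) / 2.0)

    qbar_b, p2 = make_bed_curves(bed)
    if variable_fields:
        amp_A = 0.2 * rng.random()
        amp_m = 0.15 * rng.random()
        A1 = lambda x, A=A, amp=amp_A, L=L: A * (1.0 + amp * np.sin(2 * np.pi * x / L))
        m = lambda x, amp=amp_m, L=L: 1.0 - amp * (0.5 + 0.5 * np.cos(2 * np.pi * x / L))
        model = PatientModel(L=L, A1=A1, m=m, K=K, alpha_b=alpha_b,
                             eta_b=ETA_B, eta_e=ETA_E, p_star=p_star,
                             qbar_b=qbar_b, p2=p2, bed=None,
                             name=f"random-{seed}")
    else:
        model = PatientModel(L=L, A1=A, m=1.0, K=K, alpha_b=alpha_b,
                             eta_b=ETA_B, eta_e=ETA_E, p_star=p_star,
                             qbar_b=qbar_b, p2=p2, bed=bed,
                             name=f"random-{seed}")
    model.validate()
    return model
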