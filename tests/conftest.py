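import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import emboflow as ef
from emboflow.model_core import FractionalFlow

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_K():
    model = ef.patient_fixture("K")
    return model, ef.build_fractional_flow(model)


@pytest.fixture(scope="session")
def fixture_S():
    model = ef.patient_fixture("S")
    return model, ef.build_fractional_flow(model)


@pytest.fixture(scope="session")
def quadratic_flux():
    """Mobility-ratio flux with quadratic relative permeabilities and the
    clinical viscosities (blood 4 cP, agent 18 cP)."""
    model = ef.PatientModel(
        L=1.0, A1=1.0, m=1.0, K=1.0, alpha_b=2.0, eta_b=0.04, eta_e=0.18,
        p_star=100.0, qbar_b=lambda s: 1.0, p2=lambda s: 10.0,
    )
    return ef.build_fractional_flow(model, alpha_e=2.0)


@pytest.fixture(scope="session")
def linear_flux():
    """Identity flux f(S) = S: the exact-advection regression flux."""
    return FractionalFlow(
        f=lambda s: np.asarray(s, dtype=float),
        df=lambda s: np.ones_like(np.asarray(s, dtype=float)),
    )


def make_unit_model(alpha_b=1.0, A=1.0, m=1.0, K=1.0, eta_b=0.04,
                    qbar=None, p2=None, p_star=100.0):
    """Minimal constant-coefficient patient for operator-level tests."""
    return ef.PatientModel(
        L=1.0, A1=A, m=m, K=K, alpha_b=alpha_b, eta_b=eta_b, eta_e=0.18,
        p_star=p_star,
        qbar_b=qbar if qbar is not None else (lambda s: 1.0),
        p2=p2 if p2 is not None else (lambda s: 10.0),
    )
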