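import math

import numpy as np
import pytest

import metahist as mh

C = 1e-9  # cell volume, cm^3


@pytest.fixture(scope="session")
def patient1_record():
    return mh.PatientRecord("p1", V=57.9, W=63.7, S_v=27.0, surgery=True)


@pytest.fixture(scope="session")
def patient1_params():
    """Printed fit of the surgery patient, volumes converted to cell counts."""
    return mh.ModelParams(
        A=1.85 / C, M=29.74 / C, a0=3.62e-4, b0=12.00, b1=3.41,
        variant=mh.Variant.SURGERY,
    )


@pytest.fixture(scope="session")
def patient1_bio(patient1_params, patient1_record):
    return mh.biological_from_model(patient1_params, patient1_record)


@pytest.fixture(scope="session")
def patient3_record():
    return mh.PatientRecord("p3", V=75.7, W=80.1, S_v=20.0, surgery=False)


@pytest.fixture(scope="session")
def patient3_params():
    return mh.ModelParams(
        A=2.46 / C, M=42.00 / C, a0=2.88e-6, a1=-5.03, b0=0.49, b1=0.01,
        variant=mh.Variant.FULL,
    )


def toy_history(a0=0.1, b0=5.0, b1=1.0, a1=None, A=2.0, M=20.0, resected=True,
                T=1.0, dt=1.0):
    """Biological parameters and record realizing given model parameters at
    toy scale (sizes equal the cm^3 numbers: work with c = 1, m = 0.5)."""
    g1 = math.log(A) / dt
    rho = 1.0 / (b1 * g1)
    g0 = 1.0 / (b0 * rho)
    tauV = math.log(M / A) / g0
    theta = 0.5
    beta0 = a0 * g0 / theta
    if resected:
        beta1 = -math.inf
    else:
        beta1 = (a1 if a1 is not None else -2.0) * g1 / theta
    V = T + tauV
    W = V + dt
    bio = mh.BiologicalParams(
        beta0=beta0, beta1=beta1, gamma0=g0, gamma1=g1, rho=rho, theta=theta, T=T,
    )
    rec = mh.PatientRecord("toy", V=V, W=W, S_v=1.0, surgery=resected)
    return bio, rec


def cell_scale_truth(a0=0.05, b0=2.0, b1=1.0, a1=None, A_cm3=6.0, M_cm3=30.0,
                     resected=True, V=60.0, dt=2.0, theta=0.01):
    """Biological parameters and record realizing given model parameters in
    cell-count units (c = 1e-9 cm^3, m = 0.5 cm^3), for simulator/fit tests."""
    A = A_cm3 / C
    M = M_cm3 / C
    g1 = math.log(A) / dt
    rho = 1.0 / (b1 * g1)
    g0 = 1.0 / (b0 * rho)
    tauV = math.log(M / A) / g0
    # with theta = 0 the primary growth rates drop out of the size density;
    # any positive beta0 realizes a0 = 0
    beta0 = a0 * g0 / theta if theta > 0 else 1.0
    if resected:
        beta1 = -math.inf
    elif theta > 0:
        beta1 = (a1 if a1 is not None else -2.0) * g1 / theta
    else:
        beta1 = -1.0
    T = V - tauV
    W = V + dt
    bio = mh.BiologicalParams(
        beta0=beta0, beta1=beta1, gamma0=g0, gamma1=g1, rho=rho, theta=theta, T=T,
    )
    rec = mh.PatientRecord(
        "toy", V=V, W=W, S_v=math.exp(beta0 * tauV) * C, surgery=resected,
    )
    return bio, rec


@pytest.fixture(scope="session")
def balanced_truth():
    """Truth whose size density puts substantial mass on both branches
    (~29% below the breakpoint: the informative regime for the growth-ratio
    estimator)."""
    return cell_scale_truth()
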