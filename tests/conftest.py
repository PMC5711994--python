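import numpy as np
import pytest

from landcox.models import CoxTDModel, IllnessDeathRates, OUParams


@pytest.fixture(scope="session")
def std_model() -> CoxTDModel:
    """Reference time-dependent Cox model: constant baseline hazard 0.1,
    constant log hazard ratio 1."""
    return CoxTDModel.from_constants(0.1, 1.0)


@pytest.fixture(scope="session")
def std_rates(std_model) -> IllnessDeathRates:
    """Irreversible illness-death rates tied to the reference model, with
    response rate 0.2."""
    return IllnessDeathRates.from_cox_model(std_model, 0.2)


@pytest.fixture(scope="session")
def ou_ref() -> OUParams:
    """Reference OU covariate process: total variance 0.5, intraclass
    correlation 0.5, mean-reversal rate 1."""
    return OUParams(sigma_tot_sq=0.5, rho_ic=0.5, theta=1.0)


def constant_rate_P(l01: float, l02: float, l12: float, delta: float) -> np.ndarray:
    """Closed-form transition probabilities of the irreversible model with
    constant rates over an elapsed time delta (independent of the ODE
    solver): P00 = e^{-(l01+l02) d}, P11 = e^{-l12 d},
    P01 = l01 (e^{-l12 d} - e^{-(l01+l02) d}) / (l01 + l02 - l12)."""
    a = l01 + l02
    P00 = np.exp(-a * delta)
    P11 = np.exp(-l12 * delta)
    if abs(a - l12) < 1e-12:
        P01 = l01 * delta * np.exp(-a * delta)
    else:
        P01 = l01 * (np.exp(-l12 * delta) - np.exp(-a * delta)) / (a - l12)
    P = np.array(
        [
            [P00, P01, 1.0 - P00 - P01],
            [0.0, P11, 1.0 - P11],
            [0.0, 0.0, 1.0],
        ]
    )
    return P
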