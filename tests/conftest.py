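import numpy as np
import pytest

from glifa import DelayModelParameters, archetype, hill
from glifa.synthetic_data import ARCHETYPE_GROUPS

ALL_GROUPS = list(ARCHETYPE_GROUPS)


@pytest.fixture(scope="session")
def archetypes():
    """All eight group archetypes, loaded once."""
    return {g: archetype(g) for g in ALL_GROUPS}


@pytest.fixture(scope="session")
def control_pre(archetypes):
    return archetypes["control-pre"]


@pytest.fixture(scope="session")
def ifg_pre(archetypes):
    return archetypes["ifg-pre"]


def constructed_params(G_b=90.0, I_b=10.0, F_b=400.0, S_i=1e-4, S_g=0.03,
                       sigma1=12.0, sigma2=0.2, alpha=150.0, sigma=300.0,
                       gamma=2.0, beta=3.0, g0=1.0, g1=25.0, I2=15.0,
                       kappa=2.5, tau=5.0):
    """Delay-model parameters built by back-substitution so that the chosen
    (G_b, I_b, F_b) is exactly the equilibrium."""
    hepatic = (S_i * I_b + S_g) * G_b
    d_i = (sigma1 * hill(G_b, alpha, gamma) + sigma2 * hill(F_b, sigma, beta)) / I_b
    d_f = (g0 + g1 / (1.0 + (I_b / I2) ** kappa)) / F_b
    return DelayModelParameters(
        S_i=S_i, S_g=S_g, hepatic_input=hepatic, d_i=d_i, sigma1=sigma1,
        sigma2=sigma2, alpha=alpha, sigma=sigma, gamma=gamma, beta=beta,
        g0=g0, g1=g1, I2=I2, kappa=kappa, d_f=d_f, tau=tau,
    )


@pytest.fixture
def constructed():
    """Parameters with known equilibrium (90, 10, 400)."""
    return constructed_params()


def random_physiological_params(rng: np.random.Generator) -> DelayModelParameters:
    """Log-uniform draw over broad physiological ranges (positivity suite)."""

    def lu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return DelayModelParameters(
        S_i=lu(1e-7, 1e-3), S_g=lu(0.005, 0.1), hepatic_input=lu(0.5, 10.0),
        d_i=lu(0.05, 1.0), sigma1=lu(2.0, 30.0), sigma2=lu(1e-3, 1.0),
        alpha=lu(80.0, 300.0), sigma=lu(100.0, 800.0),
        gamma=float(rng.uniform(1.0, 6.0)), beta=float(rng.uniform(1.0, 8.0)),
        g0=lu(0.3, 5.0), g1=lu(5.0, 50.0), I2=lu(5.0, 50.0),
        kappa=float(rng.uniform(1.0, 6.0)), d_f=lu(0.02, 2.0),
        tau=lu(0.5, 20.0),
    )
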