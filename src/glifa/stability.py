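"""Linear stability analysis of the delay model at its basal state.

Linearizing about the equilibrium gives a transcendental characteristic
equation

    Delta(lambda) = lambda^3 + (b1+b2) lambda^2 + (b1 b2 + b3) lambda
                    - b4 lambda e^(-lambda tau) + b1 b3 - b4 d_f e^(-lambda tau)

whose coefficients collect the Jacobian entries at the equilibrium:

    b1 = S_i I_b + S_g            (glucose self-regulation)
    b2 = d_i + d_f                (insulin + FFA clearance)
    b3 = d_i d_f - Bhat Chat      (clearance minus the FFA->insulin->FFA loop)
    b4 = S_i G_b Ahat             (delayed glucose->insulin->glucose loop)

with the secretion/lipolysis sensitivities Ahat (< 0), Bhat (<= 0) and
Chat (>= 0) defined below. Two questions are answered:

* tau = 0: the Routh-Hurwitz criterion on the resulting cubic.
* any tau: a delay-induced loss of stability requires a purely imaginary
  characteristic root +-i*omega; substituting lambda = i*omega reduces to
  the cubic p(u) = u^3 + c2 u^2 + c1 u + c0 in u = omega^2. If p has no
  positive root (in particular, by Descartes' rule, whenever c2, c1, c0 > 0)
  the equilibrium is asymptotically stable for every delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .model_core import DelayModelParameters, _delay_deriv
from .steady_state import BasalState, solve_steady_state

__all__ = [
    "CharacteristicCoefficients",
    "StabilityReport",
    "characteristic_coefficients",
    "routh_hurwitz_no_delay",
    "p_coefficients",
    "delay_independent_stability",
    "jacobian_no_delay",
]


class CharacteristicCoefficients(NamedTuple):
    b1: float
    b2: float
    b3: float
    b4: float
    A_hat: float
    B_hat: float
    C_hat: float


@dataclass(frozen=True)
class StabilityReport:
    """Full stability verdict for one parameter set.

    ``descartes_sufficient`` records the sufficient condition
    c2, c1, c0 > 0; ``positive_u_roots`` is the exhaustive numerical check
    (positive real roots u = omega^2 of p(u), each a candidate pure
    imaginary pair +-i*omega). The two are reported separately because
    positivity of the c_i is sufficient but not necessary for the absence
    of positive roots.
    """

    equilibrium: BasalState
    b1: float
    b2: float
    b3: float
    b4: float
    A_hat: float
    B_hat: float
    C_hat: float
    c2: float
    c1: float
    c0: float
    stable_no_delay: bool
    descartes_sufficient: bool
    positive_u_roots: tuple = field(default_factory=tuple)

    @property
    def delay_independent_stable(self) -> bool:
        return self.stable_no_delay and len(self.positive_u_roots) == 0


def characteristic_coefficients(
    p: DelayModelParameters, eq: BasalState, check_tol: float = 1e-6
) -> CharacteristicCoefficients:
    """Coefficients b1..b4 and sensitivities Ahat, Bhat, Chat at ``eq``.

    ``eq`` must be the solved equilibrium of ``p``; the function refuses
    inconsistent inputs (vector field residual above ``check_tol``).
    """
    G_b, I_b, F_b = eq.G_b, eq.I_b, eq.F_b
    resid = max(abs(d) for d in _delay_deriv(G_b, I_b, F_b, G_b, p))
    if resid > check_tol:
        raise ValueError(
            f"characteristic_coefficients: state is not an equilibrium of the "
            f"parameters (residual {resid:g} > {check_tol:g})"
        )
    a_g = p.alpha**p.gamma
    A_hat = -a_g * p.gamma * p.sigma1 * G_b ** (p.gamma - 1) / (a_g + G_b**p.gamma) ** 2
    s_b = p.sigma**p.beta
    B_hat = -p.sigma2 * p.beta * F_b ** (p.beta - 1) * s_b / (s_b + F_b**p.beta) ** 2
    r = (I_b / p.I2) ** p.kappa
    C_hat = p.g1 * p.kappa * (I_b / p.I2) ** (p.kappa - 1) / (p.I2 * (1.0 + r) ** 2)
    b1 = p.S_i * I_b + p.S_g
    b2 = p.d_i + p.d_f
    b3 = p.d_i * p.d_f - B_hat * C_hat
    b4 = p.S_i * G_b * A_hat
    return CharacteristicCoefficients(b1, b2, b3, b4, A_hat, B_hat, C_hat)


def routh_hurwitz_no_delay(b1: float, b2: float, b3: float, b4: float, d_f: float) -> bool:
    """Routh-Hurwitz verdict for the tau = 0 characteristic cubic.

    The cubic is lambda^3 + (b1+b2) lambda^2 + (b1 b2 + b3 - b4) lambda
    + b1 b3 - d_f b4; stability requires all coefficients positive and
    (b1+b2)(b1 b2 + b3 - b4) > b1 b3 - d_f b4.
    """
    a1 = b1 + b2
    a2 = b1 * b2 + b3 - b4
    a3 = b1 * b3 - d_f * b4
    return a1 > 0 and a2 > 0 and a3 > 0 and a1 * a2 > a3


def p_coefficients(
    b1: float, b2: float, b3: float, b4: float, d_f: float
) -> tuple[float, float, float]:
    """Coefficients (c2, c1, c0) of the reduced cubic p(u) in u = omega^2."""
    c2 = (b1 + b2) ** 2 - 2.0 * (b1 * b2 + b3)
    c1 = (b1 * b2 + b3) ** 2 - 2.0 * b1 * b3 * (b1 + b2) - b4**2
    c0 = (b1 * b3) ** 2 - (b4 * d_f) ** 2
    return c2, c1, c0


def _positive_real_roots(c2: float, c1: float, c0: float) -> tuple:
    """Positive real roots of p(u), via companion-matrix eigenvalues."""
    roots = np.roots([1.0, c2, c1, c0])
    out = []
    for r in roots:
        if abs(r.imag) < 1e-9 * max(1.0, abs(r.real)) and r.real > 1e-12:
            out.append(float(r.real))
    return tuple(sorted(out))


def delay_independent_stability(
    p: DelayModelParameters, tol: float = 1e-9
) -> StabilityReport:
    """Full pipeline: equilibrium -> coefficients -> both stability checks."""
    eq = solve_steady_state(p, tol=tol)
    b1, b2, b3, b4, A_hat, B_hat, C_hat = characteristic_coefficients(p, eq)
    c2, c1, c0 = p_coefficients(b1, b2, b3, b4, p.d_f)
    return StabilityReport(
        equilibrium=eq,
        b1=b1,
        b2=b2,
        b3=b3,
        b4=b4,
        A_hat=A_hat,
        B_hat=B_hat,
        C_hat=C_hat,
        c2=c2,
        c1=c1,
        c0=c0,
        stable_no_delay=routh_hurwitz_no_delay(b1, b2, b3, b4, p.d_f),
        descartes_sufficient=(c2 > 0 and c1 > 0 and c0 > 0),
        positive_u_roots=_positive_real_roots(c2, c1, c0),
    )


def jacobian_no_delay(p: DelayModelParameters, eq: BasalState) -> np.ndarray:
    """Analytic 3x3 Jacobian of the tau = 0 vector field at the equilibrium.

    Provided for eigenvalue cross-checks of the Routh-Hurwitz verdict.
    """
    b1, b2, b3, b4, A_hat, B_hat, C_hat = characteristic_coefficients(p, eq)
    return np.array(
        [
            [-b1, -p.S_i * eq.G_b, 0.0],
            [-A_hat, -p.d_i, -B_hat],
            [0.0, -C_hat, -p.d_f],
        ]
    )
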