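"""Unique equilibrium (basal state) of the delay model.

Setting the three derivatives to zero and eliminating G and F leaves a
single scalar equation in the equilibrium insulin level I*:

    sigma1 * H(G*(I*)) + sigma2 * H(F*(I*)) - d_i * I* = 0,

with G*(I*) = hepatic_input / (S_i*I* + S_g) and
F*(I*) = (g0 + g1 / (1 + (I*/I2)**kappa)) / d_f.

Both Hill terms are decreasing in I* (G* and F* fall as insulin rises) and
the degradation term -d_i*I* is strictly decreasing, so the residual is
strictly decreasing and crosses zero exactly once: the model has a unique
positive equilibrium, the basal state (G_b, I_b, F_b).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .model_core import DelayModelParameters, SystemState, _delay_deriv, hill

__all__ = ["BasalState", "EquilibriumError", "equilibrium_residual", "solve_steady_state"]


class EquilibriumError(RuntimeError):
    """Raised when no positive equilibrium can be bracketed."""


@dataclass(frozen=True)
class BasalState:
    """The solved equilibrium of the delay model.

    ``residual_norm`` is the max absolute component of the model vector
    field evaluated at the solution — a direct certificate of equilibrium
    quality.
    """

    G_b: float
    I_b: float
    F_b: float
    residual_norm: float

    def as_state(self) -> SystemState:
        return SystemState(self.G_b, self.I_b, self.F_b)


def _G_star(I_star: float, p: DelayModelParameters) -> float:
    return p.hepatic_input / (p.S_i * I_star + p.S_g)


def _F_star(I_star: float, p: DelayModelParameters) -> float:
    return (p.g0 + p.g1 / (1.0 + (I_star / p.I2) ** p.kappa)) / p.d_f


def equilibrium_residual(I_star: float, p: DelayModelParameters) -> float:
    """Insulin-balance residual at candidate equilibrium insulin ``I_star``.

    Positive below the equilibrium, negative above it; strictly decreasing.
    """
    if I_star <= 0:
        raise ValueError(f"equilibrium_residual: I_star must be positive, got {I_star}")
    return (
        p.sigma1 * hill(_G_star(I_star, p), p.alpha, p.gamma)
        + p.sigma2 * hill(_F_star(I_star, p), p.sigma, p.beta)
        - p.d_i * I_star
    )


def solve_steady_state(p: DelayModelParameters, tol: float = 1e-9) -> BasalState:
    """Solve for the unique basal state (G_b, I_b, F_b).

    Brackets the sign change of :func:`equilibrium_residual` on
    [1e-6, 1e6] uU/ml (expanding if necessary), refines with Brent's
    method, then back-substitutes G_b and F_b. Raises
    :class:`EquilibriumError` if no sign change exists — e.g. for the
    degenerate boundary case sigma1 = sigma2 = 0 whose formal equilibrium
    I* = 0 violates positivity.
    """
    lo, hi = 1e-6, 1e6
    f_lo, f_hi = equilibrium_residual(lo, p), equilibrium_residual(hi, p)
    n_expand = 0
    while f_lo * f_hi > 0 and n_expand < 6:
        lo, hi = lo * 1e-2, hi * 1e2
        f_lo, f_hi = equilibrium_residual(lo, p), equilibrium_residual(hi, p)
        n_expand += 1
    if f_lo * f_hi > 0 or not (np.isfinite(f_lo) and np.isfinite(f_hi)):
        raise EquilibriumError(
            "no positive equilibrium: residual does not change sign on "
            f"[{lo:g}, {hi:g}] (residual({lo:g})={f_lo:g}, residual({hi:g})={f_hi:g}); "
            "parameters are inconsistent with a positive basal insulin level"
        )
    I_b = brentq(equilibrium_residual, lo, hi, args=(p,), xtol=1e-10, rtol=8.9e-16)
    G_b = _G_star(I_b, p)
    F_b = _F_star(I_b, p)
    residual = max(abs(d) for d in _delay_deriv(G_b, I_b, F_b, G_b, p))
    if residual > tol:
        raise EquilibriumError(
            f"equilibrium residual {residual:g} exceeds tolerance {tol:g}"
        )
    return BasalState(G_b=G_b, I_b=I_b, F_b=F_b, residual_norm=residual)
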