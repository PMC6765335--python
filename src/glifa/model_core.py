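"""Parameter and state types plus the vector fields of the two IVGTT models.

Two models of the glucose-insulin-free-fatty-acid (FFA) axis during an
intravenous glucose tolerance test are implemented:

* an explicit time-delay model in which plasma insulin ``I`` is a state
  variable and glucose-stimulated secretion acts through a Hill function of
  the glucose concentration ``tau`` minutes in the past, and
* a Bergman-style minimal model in which plasma insulin is an external
  forcing and a remote-insulin compartment ``X`` mediates glucose removal.

Units are fixed throughout the package: minutes, mg/dl for glucose, uU/ml
for insulin, uM for FFA. There is no unit-conversion layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np

__all__ = [
    "DelayModelParameters",
    "MinimalModelParameters",
    "SystemState",
    "InsulinForcing",
    "hill",
    "delay_rhs",
    "minimal_rhs",
]


def hill(x: float, half: float, exponent: float) -> float:
    """Saturating Hill response ``x**n / (half**n + x**n)``.

    Strictly increasing in ``x``, equal to 1/2 at ``x == half`` and
    approaching 1 as ``x -> inf``.

    Parameters
    ----------
    x : float
        Nonnegative stimulus concentration.
    half : float
        Positive half-saturation constant (same units as ``x``).
    exponent : float
        Hill coefficient, ``>= 1`` for the sigmoidal responses used here.
    """
    if x < 0:
        raise ValueError(f"hill: x must be nonnegative, got {x}")
    if half <= 0:
        raise ValueError(f"hill: half-saturation must be positive, got {half}")
    if x == 0.0:
        return 0.0
    # work with the ratio to avoid overflow for large x**n
    r = (half / x) ** exponent
    return 1.0 / (1.0 + r)


def _require_positive(obj, names, strict=True):
    for name in names:
        v = getattr(obj, name)
        if not math.isfinite(v):
            raise ValueError(f"{type(obj).__name__}.{name} must be finite, got {v}")
        if strict and v <= 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be > 0, got {v}")
        if not strict and v < 0:
            raise ValueError(f"{type(obj).__name__}.{name} must be >= 0, got {v}")


@dataclass(frozen=True)
class DelayModelParameters:
    """Parameters of the explicit time-delay glucose-insulin-FFA model.

    The hepatic glucose input ``(S_i*I_b + S_g)*G_b`` is stored lumped as a
    single constant ``hepatic_input`` because that is how it is estimated;
    basal levels are recovered downstream by solving for the equilibrium.

    Attributes
    ----------
    S_i : insulin sensitivity, ml/(uU*min)
    S_g : glucose effectiveness, 1/min
    hepatic_input : lumped constant average hepatic glucose input, mg/(dl*min)
    d_i : insulin degradation rate, 1/min
    sigma1 : maximal glucose-stimulated insulin secretion rate, uU/(mg*min)
    sigma2 : FFA-stimulated insulin secretion rate, 1/min
    alpha : glucose half-saturation, mg/dl
    sigma : FFA half-saturation, uM
    gamma, beta, kappa : Hill exponents (unitless, >= 1)
    g0 : nonsuppressible lipolysis rate, uM/min
    g1 : suppressible lipolysis span, uM/min (maximal lipolysis is g0+g1)
    I2 : insulin threshold for lipolysis inhibition, uU/ml
    d_f : FFA clearance rate, 1/min
    tau : glucose-stimulated secretion delay, min (>= 0)
    """

    S_i: float
    S_g: float
    hepatic_input: float
    d_i: float
    sigma1: float
    sigma2: float
    alpha: float
    sigma: float
    gamma: float
    beta: float
    g0: float
    g1: float
    I2: float
    kappa: float
    d_f: float
    tau: float

    def __post_init__(self):
        # sigma1/sigma2 may be zero (secretion pathway switched off), which
        # is useful for decoupled closed-form checks; everything else that
        # scales a loss or saturation must be strictly positive.
        _require_positive(
            self,
            ["S_i", "S_g", "hepatic_input", "d_i", "alpha", "sigma", "g0", "g1", "I2", "d_f"],
        )
        _require_positive(self, ["sigma1", "sigma2", "tau"], strict=False)
        for name in ("gamma", "beta", "kappa"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 1):
                raise ValueError(f"DelayModelParameters.{name} must be >= 1, got {v}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class MinimalModelParameters:
    """Parameters of the minimal (remote-insulin compartment) model.

    Attributes
    ----------
    S_G : glucose effectiveness, 1/min
    S_I : insulin sensitivity, ml/(uU*min)
    c_X : remote-insulin equilibration rate, 1/min
    l0 : nonsuppressible lipolysis rate, uM/min
    l2 : suppressible lipolysis span, uM/min
    X2 : remote-insulin threshold for lipolysis inhibition
    A : Hill exponent of lipolysis inhibition (unitless, >= 1)
    c_f : FFA clearance rate, 1/min
    G_b : basal glucose, mg/dl
    I_b : basal insulin, uU/ml
    """

    S_G: float
    S_I: float
    c_X: float
    l0: float
    l2: float
    X2: float
    A: float
    c_f: float
    G_b: float
    I_b: float

    def __post_init__(self):
        _require_positive(
            self, ["S_G", "S_I", "c_X", "l0", "l2", "X2", "c_f", "G_b", "I_b"]
        )
        if not (math.isfinite(self.A) and self.A >= 1):
            raise ValueError(f"MinimalModelParameters.A must be >= 1, got {self.A}")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SystemState:
    """A positive state point (G, I-or-X, F).

    For the delay model the middle component is plasma insulin ``I``;
    for the minimal model it is remote insulin ``X``, which may legitimately
    sit at zero when plasma insulin equals basal. G and F are strictly
    positive.
    """

    G: float
    I_or_X: float
    F: float

    def __post_init__(self):
        _require_positive(self, ["G", "F"])
        _require_positive(self, ["I_or_X"], strict=False)

    def as_array(self) -> np.ndarray:
        return np.array([self.G, self.I_or_X, self.F], dtype=float)


@dataclass(frozen=True)
class InsulinForcing:
    """Plasma-insulin time course used to force the minimal model.

    Piecewise-linear interpolation between samples, constant extrapolation
    beyond both ends — the standard minimal-model convention for measured
    insulin.
    """

    times: np.ndarray
    values: np.ndarray
    interpolation: str = "linear"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape or t.size < 2:
            raise ValueError("InsulinForcing needs matching 1-d arrays with >= 2 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("InsulinForcing times must be strictly increasing")
        if np.any(v <= 0):
            raise ValueError("InsulinForcing values must be positive")
        if self.interpolation != "linear":
            raise ValueError(f"unknown interpolation rule {self.interpolation!r}")

    def __call__(self, t):
        return np.interp(t, self.times, self.values)

    @classmethod
    def constant(cls, level: float, t_end: float = 1e6) -> "InsulinForcing":
        return cls(np.array([0.0, t_end]), np.array([level, level]))


# -- vector fields ----------------------------------------------------------
#
# The private float versions are what the integrators call; the public
# functions validate and delegate.


def _delay_deriv(G, I, F, G_delayed, p: DelayModelParameters):
    dG = p.hepatic_input - p.S_i * G * I - p.S_g * G
    dI = (
        p.sigma1 * hill(G_delayed, p.alpha, p.gamma)
        + p.sigma2 * hill(F, p.sigma, p.beta)
        - p.d_i * I
    )
    dF = p.g0 + p.g1 / (1.0 + (I / p.I2) ** p.kappa) - p.d_f * F
    return dG, dI, dF


def _minimal_deriv(G, X, F, I_t, p: MinimalModelParameters):
    dG = p.S_G * p.G_b - (p.S_G + p.S_I * X) * G
    dX = p.c_X * (I_t - X - p.I_b)
    # X may transiently dip below 0 when forcing insulin falls under basal;
    # remote-insulin action on lipolysis is then absent, not negative
    Xp = X if X > 0.0 else 0.0
    dF = p.l0 + p.l2 / (1.0 + (Xp / p.X2) ** p.A) - p.c_f * F
    return dG, dX, dF


def delay_rhs(
    current: SystemState, G_delayed: float, p: DelayModelParameters
) -> tuple[float, float, float]:
    """Time derivative (G', I', F') of the delay model at ``current``.

    ``G_delayed`` is the glucose concentration ``tau`` minutes in the past,
    supplied by the caller (the integrator's history lookup).
    """
    if G_delayed <= 0:
        raise ValueError(f"delay_rhs: delayed glucose must be positive, got {G_delayed}")
    return _delay_deriv(current.G, current.I_or_X, current.F, G_delayed, p)


def minimal_rhs(
    current: SystemState, I_t: float, p: MinimalModelParameters
) -> tuple[float, float, float]:
    """Time derivative (G', X', F') of the minimal model at ``current``.

    ``I_t`` is the forcing plasma-insulin concentration at the current time.
    """
    if I_t < 0:
        raise ValueError(f"minimal_rhs: forcing insulin must be nonnegative, got {I_t}")
    return _minimal_deriv(current.G, current.I_or_X, current.F, I_t, p)
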