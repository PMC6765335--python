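"""Independent numerical oracles used by the test suite.

Everything here is written directly from the model equations, deliberately
NOT reusing the package's vector-field or solver code, so that agreement
between the two routes is informative.
"""

from __future__ import annotations

import numpy as np


def _hill(x, half, n):
    return x**n / (half**n + x**n)


def delay_field(y, G_lag, p):
    """Delay-model right-hand side written out longhand."""
    G, I, F = y
    dG = p.hepatic_input - p.S_i * G * I - p.S_g * G
    dI = (
        p.sigma1 * _hill(G_lag, p.alpha, p.gamma)
        + p.sigma2 * _hill(F, p.sigma, p.beta)
        - p.d_i * I
    )
    dF = p.g0 + p.g1 / (1.0 + (I / p.I2) ** p.kappa) - p.d_f * F
    return np.array([dG, dI, dF])


def rk4_delay(p, y0, t_end, h, history_G=None):
    """Fixed-step classical RK4 method-of-steps integration of the DDE.

    The lagged glucose is looked up by linear interpolation on the
    already-computed step grid; the constant history covers s <= 0. Stage
    times never look ahead of the current step because tau >= h is
    required.
    """
    tau = p.tau
    if tau > 0 and h > tau:
        raise ValueError("oracle requires h <= tau")
    n = int(round(t_end / h))
    ts = np.arange(n + 1) * h
    Y = np.empty((n + 1, 3))
    Y[0] = y0
    G0 = y0[0] if history_G is None else history_G

    def G_lag(t, i_done, step_start):
        # The bolus makes G discontinuous at t = 0, so the lagged input
        # jumps at t = tau. Steps that end at the jump keep the history
        # value at their endpoint stage; steps that start at (or after)
        # the jump use the trajectory value G(0) there.
        s = t - tau
        tol = 1e-9 * max(1.0, tau)  # float jitter in t = i*h near the jump
        if s < -tol or (abs(s) <= tol and step_start < tau - tol):
            return G0
        if abs(s) <= tol:
            return Y[0, 0]
        x = s / h
        i = min(int(x), i_done - 1)
        w = x - i
        return (1.0 - w) * Y[i, 0] + w * Y[i + 1, 0]

    for i in range(n):
        t = ts[i]
        y = Y[i]
        if tau == 0.0:
            k1 = delay_field(y, y[0], p)
            y2 = y + 0.5 * h * k1
            k2 = delay_field(y2, y2[0], p)
            y3 = y + 0.5 * h * k2
            k3 = delay_field(y3, y3[0], p)
            y4 = y + h * k3
            k4 = delay_field(y4, y4[0], p)
        else:
            k1 = delay_field(y, G_lag(t, i + 1, t), p)
            k2 = delay_field(y + 0.5 * h * k1, G_lag(t + 0.5 * h, i + 1, t), p)
            k3 = delay_field(y + 0.5 * h * k2, G_lag(t + 0.5 * h, i + 1, t), p)
            k4 = delay_field(y + h * k3, G_lag(t + h, i + 1, t), p)
        Y[i + 1] = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return ts, Y


def rk4_minimal(p, y0, forcing, t_end, h):
    """Fixed-step RK4 for the forced minimal model."""

    def field(y, t):
        G, X, F = y
        I_t = float(forcing(t))
        dG = p.S_G * p.G_b - (p.S_G + p.S_I * X) * G
        dX = p.c_X * (I_t - X - p.I_b)
        Xp = max(X, 0.0)
        dF = p.l0 + p.l2 / (1.0 + (Xp / p.X2) ** p.A) - p.c_f * F
        return np.array([dG, dX, dF])

    n = int(round(t_end / h))
    ts = np.arange(n + 1) * h
    Y = np.empty((n + 1, 3))
    Y[0] = y0
    for i in range(n):
        t, y = ts[i], Y[i]
        k1 = field(y, t)
        k2 = field(y + 0.5 * h * k1, t + 0.5 * h)
        k3 = field(y + 0.5 * h * k2, t + 0.5 * h)
        k4 = field(y + h * k3, t + h)
        Y[i + 1] = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    return ts, Y


def numerical_jacobian(p, eq, h=1e-20):
    """Complex-step Jacobian of the tau = 0 delay field at a point.

    The complex-step derivative Im[f(x + ih)]/h has no subtractive
    cancellation, which matters here: some Hill-term sensitivities are ~1e-8
    against function values ~1e1, where central differences lose most
    digits. All model expressions are analytic, so the complex extension is
    exact.
    """
    y0 = np.array([eq.G_b, eq.I_b, eq.F_b], dtype=complex)
    J = np.empty((3, 3))
    for j in range(3):
        y = y0.copy()
        y[j] += 1j * h
        J[:, j] = np.imag(delay_field(y, y[0], p)) / h
    return J
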