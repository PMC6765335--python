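"""Numerical integration of both models over the IVGTT horizon.

The delay model is integrated by the method of steps: the constant
pre-bolus history G(s) = G(0) for s in [-tau, 0] makes the lagged term a
known function on each interval [k*tau, (k+1)*tau], so the DDE reduces to a
sequence of ODE solves, each taking the lagged glucose from the dense
interpolant of the previous segment. Segment boundaries are solver restart
points, which respects the derivative discontinuities the constant history
introduces at multiples of tau.

The minimal model is a plain ODE forced by a plasma-insulin time course.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import (
    DelayModelParameters,
    InsulinForcing,
    MinimalModelParameters,
    SystemState,
    _delay_deriv,
    _minimal_deriv,
)

__all__ = ["StateTrajectory", "SimulationError", "simulate_delay", "simulate_minimal"]

#: IVGTT sampling protocol: post-bolus draw times in minutes.
PROTOCOL_TIMES = np.array(
    [2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 19, 22, 25, 30, 40, 50, 60, 70, 80,
     100, 120, 140, 160, 180],
    dtype=float,
)

#: Pre-bolus baseline draw times in minutes.
PRE_BOLUS_TIMES = np.array([-15.0, -10.0, -5.0])


class SimulationError(RuntimeError):
    """Integration failure or loss of positivity, with the offending time."""


@dataclass(frozen=True)
class StateTrajectory:
    """Dense model trajectory on an output grid.

    ``I`` holds plasma insulin for the delay model and remote insulin X for
    the minimal model (see ``meta['model']``).
    """

    times: np.ndarray
    G: np.ndarray
    I: np.ndarray
    F: np.ndarray
    meta: dict = field(default_factory=dict)

    def at(self, t: float) -> SystemState:
        i = int(np.argmin(np.abs(self.times - t)))
        return SystemState(self.G[i], self.I[i], self.F[i])


def _default_grid(t_end: float) -> np.ndarray:
    dense = np.arange(0.0, t_end + 1e-9, 1.0)
    grid = np.union1d(dense, PROTOCOL_TIMES[PROTOCOL_TIMES <= t_end])
    return np.union1d(grid, [t_end])


def _check_positive(times, ys, what):
    bad = np.where(np.min(ys, axis=0) <= 0)[0]
    if bad.size:
        t_bad = times[bad[0]]
        raise SimulationError(f"{what}: nonpositive state encountered at t = {t_bad:g} min")


def simulate_delay(
    p: DelayModelParameters,
    init: SystemState,
    t_end: float,
    output_times: np.ndarray | None = None,
    history: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
    max_segments: int = 5000,
) -> StateTrajectory:
    """Integrate the delay model from ``init`` with constant glucose history.

    ``history`` is the constant glucose level G(s) for s in [-tau, 0];
    it defaults to ``init.G``. For IVGTT runs the physiological choice is
    the pre-bolus basal glucose G_b (the subject sat at the fasting steady
    state until the bolus), which is what the dataset generator and the
    fitting layer pass; the delay is then visible as the lag before
    secretion responds to the bolus. With tau = 0 the solve degrades to a
    plain ODE. Output defaults to a 1-minute grid plus the IVGTT protocol
    times.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if history is None:
        history = init.G
    if history <= 0:
        raise ValueError(f"history glucose must be positive, got {history}")
    if output_times is None:
        output_times = _default_grid(t_end)
    else:
        output_times = np.asarray(output_times, dtype=float)
        if output_times.size and (output_times[0] < 0 or output_times[-1] > t_end + 1e-9):
            raise ValueError("output_times must lie within [0, t_end]")

    y0 = init.as_array()
    tau = p.tau

    if tau == 0.0:

        def rhs(t, y):
            return _delay_deriv(y[0], y[1], y[2], y[0], p)

        sol = solve_ivp(
            rhs, (0.0, t_end), y0, method=method, dense_output=True,
            rtol=rtol, atol=atol,
        )
        if not sol.success:
            raise SimulationError(f"delay model (tau=0) solver failed: {sol.message}")
        ys = sol.sol(output_times)
        _check_positive(output_times, ys, "delay model")
        return StateTrajectory(
            times=output_times, G=ys[0], I=ys[1], F=ys[2],
            meta={"model": "delay", "tau": 0.0, "rtol": rtol, "atol": atol,
                  "method": method, "history": history},
        )

    # Segment boundaries at multiples of tau: while integrating segment k,
    # the lagged time t - tau always falls in segment k-1 (or the constant
    # history for k = 0), so each solve only needs the previous interpolant.
    G0 = history
    if t_end / tau > max_segments:
        raise SimulationError(
            f"delay model: tau = {tau:g} needs {t_end / tau:.0f} method-of-steps "
            f"segments on [0, {t_end:g}], above the cap of {max_segments}"
        )
    boundaries = list(np.arange(0.0, t_end, tau)) + [t_end]
    segments = []  # dense interpolants, one per segment
    y = y0
    prev_dense = None
    for k, (t0, t1) in enumerate(zip(boundaries[:-1], boundaries[1:])):
        if prev_dense is None:

            def rhs(t, y):
                return _delay_deriv(y[0], y[1], y[2], G0, p)

        else:
            lag_dense = prev_dense

            def rhs(t, y, _d=lag_dense):
                s = t - tau
                # history applies for s < 0 strictly: the bolus makes G
                # discontinuous at t = 0 and the lagged value at s = 0 is
                # the post-bolus state G(0), not the pre-bolus history
                Gd = G0 if s < 0.0 else float(_d(s)[0])
                return _delay_deriv(y[0], y[1], y[2], Gd, p)

        sol = solve_ivp(
            rhs, (t0, t1), y, method=method, dense_output=True, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise SimulationError(
                f"delay model solver failed on [{t0:g}, {t1:g}]: {sol.message}"
            )
        segments.append(sol.sol)
        prev_dense = sol.sol
        y = sol.y[:, -1]

    # map each output time onto its segment
    ys = np.empty((3, output_times.size))
    idx = np.clip(np.searchsorted(boundaries, output_times, side="right") - 1, 0,
                  len(segments) - 1)
    for j, (t, k) in enumerate(zip(output_times, idx)):
        ys[:, j] = segments[k](t)
    _check_positive(output_times, ys, "delay model")
    return StateTrajectory(
        times=output_times, G=ys[0], I=ys[1], F=ys[2],
        meta={"model": "delay", "tau": tau, "rtol": rtol, "atol": atol,
              "method": method, "history": history},
    )


def simulate_minimal(
    p: MinimalModelParameters,
    forcing: InsulinForcing,
    init: SystemState,
    output_times: np.ndarray | None = None,
    t_end: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> StateTrajectory:
    """Integrate the minimal model forced by a plasma-insulin time course.

    ``init.I_or_X`` is the initial remote insulin X(0). The trajectory's
    ``I`` array holds X(t).
    """
    if t_end is None:
        t_end = float(output_times[-1]) if output_times is not None else 180.0
    if output_times is None:
        output_times = _default_grid(t_end)
    else:
        output_times = np.asarray(output_times, dtype=float)

    def rhs(t, y):
        return _minimal_deriv(y[0], y[1], y[2], float(forcing(t)), p)

    sol = solve_ivp(
        rhs, (0.0, t_end), init.as_array(), method=method, dense_output=True,
        rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(f"minimal model solver failed: {sol.message}")
    ys = sol.sol(output_times)
    if np.min(ys[0]) <= 0 or np.min(ys[2]) <= 0:
        bad = np.where((ys[0] <= 0) | (ys[2] <= 0))[0][0]
        raise SimulationError(
            f"minimal model: nonpositive G or F at t = {output_times[bad]:g} min"
        )
    return StateTrajectory(
        times=output_times, G=ys[0], I=ys[1], F=ys[2],
        meta={"model": "minimal", "rtol": rtol, "atol": atol, "method": method},
    )
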