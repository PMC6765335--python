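import numpy as np
import pytest
from dataclasses import replace

from glifa import (
    InsulinForcing,
    SystemState,
    simulate_delay,
    simulate_minimal,
    solve_steady_state,
)
from glifa.simulate import SimulationError

from conftest import random_physiological_params
from oracles import rk4_delay, rk4_minimal


class TestSimulateDelay:
    def test_pure_insulin_decay_closed_form(self, constructed):
        """With secretion off, insulin decays exponentially at rate d_i."""
        p = replace(constructed, sigma1=0.0, sigma2=0.0)
        init = SystemState(120.0, 20.0, 300.0)
        traj = simulate_delay(p, init, t_end=60.0, output_times=[60.0])
        expected = 20.0 * np.exp(-p.d_i * 60.0)
        assert traj.I[0] == pytest.approx(expected, rel=1e-6)

    def test_equilibrium_is_invariant(self, ifg_pre):
        p = ifg_pre.delay
        eq = solve_steady_state(p)
        traj = simulate_delay(p, eq.as_state(), t_end=200.0)
        for arr, ref in ((traj.G, eq.G_b), (traj.I, eq.I_b), (traj.F, eq.F_b)):
            assert np.max(np.abs(arr - ref)) / ref < 1e-6

    def test_agrees_with_fixed_step_rk4_oracle(self, ifg_pre):
        """Adaptive method-of-steps vs an independent fixed-step RK4
        method-of-steps at step 0.001 min, bolus start."""
        p = ifg_pre.delay
        eq = solve_steady_state(p)
        init = SystemState(3 * eq.G_b, eq.I_b, eq.F_b)
        check_times = [10.0, 60.0, 180.0]
        traj = simulate_delay(p, init, t_end=180.0, output_times=check_times,
                              history=eq.G_b)
        ts, Y = rk4_delay(p, init.as_array(), 180.0, h=0.001, history_G=eq.G_b)
        for j, t in enumerate(check_times):
            i = int(round(t / 0.001))
            for col, arr in enumerate((traj.G, traj.I, traj.F)):
                assert arr[j] == pytest.approx(Y[i, col], rel=1e-4)

    def test_zero_delay_equals_direct_ode_solve(self, constructed):
        from scipy.integrate import solve_ivp
        from oracles import delay_field

        p = replace(constructed, tau=0.0)
        init = SystemState(200.0, 5.0, 300.0)
        traj = simulate_delay(p, init, t_end=120.0, output_times=[30.0, 120.0],
                              rtol=1e-11, atol=1e-13)
        sol = solve_ivp(
            lambda t, y: delay_field(y, y[0], p), (0.0, 120.0), init.as_array(),
            method="LSODA", rtol=1e-11, atol=1e-13, t_eval=[30.0, 120.0],
        )
        for j in range(2):
            for col, arr in enumerate((traj.G, traj.I, traj.F)):
                assert arr[j] == pytest.approx(sol.y[col, j], rel=1e-8)

    def test_tolerance_refinement_converges(self, ifg_pre):
        p = ifg_pre.delay
        eq = solve_steady_state(p)
        init = SystemState(3 * eq.G_b, eq.I_b, eq.F_b)
        grid = [10.0, 60.0, 180.0]
        a = simulate_delay(p, init, 180.0, output_times=grid, history=eq.G_b,
                           rtol=1e-8, atol=1e-10)
        b = simulate_delay(p, init, 180.0, output_times=grid, history=eq.G_b,
                           rtol=1e-10, atol=1e-12)
        for x, y in ((a.G, b.G), (a.I, b.I), (a.F, b.F)):
            assert np.max(np.abs(x - y) / np.abs(y)) < 1e-5

    def test_positivity_and_bounds_on_random_draws(self):
        """Trajectories from random positive parameters/initial states stay
        positive, and glucose/FFA respect their invariant-region ceilings
        when started below them (short-horizon version of the positivity
        suite; the acceptance suite runs the full 200 x 1000 min study)."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = random_physiological_params(rng)
            G_cap = p.hepatic_input / p.S_g
            F_cap = (p.g0 + p.g1) / p.d_f
            init = SystemState(
                float(rng.uniform(0.1, 0.9) * G_cap),
                float(rng.uniform(1.0, 50.0)),
                float(rng.uniform(0.1, 0.9) * F_cap),
            )
            traj = simulate_delay(p, init, t_end=200.0,
                                  output_times=np.linspace(0, 200, 81),
                                  rtol=1e-6, atol=1e-8)
            assert np.all(traj.G > 0) and np.all(traj.I > 0) and np.all(traj.F > 0)
            assert np.all(traj.G <= G_cap * (1 + 1e-6))
            assert np.all(traj.F <= F_cap * (1 + 1e-6))

    def test_reports_time_of_solver_breakdown(self, constructed):
        with pytest.raises((SimulationError, ValueError)):
            simulate_delay(constructed, SystemState(1e-8, 1e-8, 1e-8), t_end=-5.0)


class TestSimulateMinimal:
    def test_basal_forcing_keeps_remote_insulin_at_zero(self, control_pre):
        p = control_pre.minimal
        forcing = InsulinForcing.constant(p.I_b)
        init = SystemState(2 * p.G_b, 0.0, 400.0)
        traj = simulate_minimal(p, forcing, init, t_end=300.0)
        assert np.max(np.abs(traj.I)) < 1e-8
        # glucose relaxes to basal exponentially at rate S_G
        expected = p.G_b + (2 * p.G_b - p.G_b) * np.exp(-p.S_G * traj.times)
        assert np.max(np.abs(traj.G - expected) / expected) < 1e-6

    def test_remote_insulin_closed_form_decay(self, control_pre):
        p = control_pre.minimal
        forcing = InsulinForcing.constant(p.I_b)
        x0 = 7.5
        traj = simulate_minimal(p, forcing, SystemState(p.G_b, x0, 400.0),
                                output_times=[0.5, 1.0], t_end=1.0)
        for j, t in enumerate((0.5, 1.0)):
            assert traj.I[j] == pytest.approx(x0 * np.exp(-p.c_X * t), rel=1e-6)

    def test_ffa_limit_under_basal_forcing(self, control_pre):
        """With X pinned at 0 the FFA equation is linear with fixed input,
        so F -> (l0 + l2)/c_f."""
        p = control_pre.minimal
        forcing = InsulinForcing.constant(p.I_b)
        traj = simulate_minimal(p, forcing, SystemState(p.G_b, 0.0, 100.0),
                                output_times=[500.0], t_end=500.0)
        assert traj.F[0] == pytest.approx((p.l0 + p.l2) / p.c_f, rel=1e-3)

    def test_agrees_with_rk4_oracle_under_synthetic_forcing(self, archetypes):
        """T2DM-post minimal model driven by a delay-model insulin curve,
        checked against fixed-step RK4."""
        arch = archetypes["t2dm-post"]
        eq = solve_steady_state(arch.delay)
        dtraj = simulate_delay(arch.delay, SystemState(3 * eq.G_b, eq.I_b, eq.F_b),
                               t_end=180.0, history=eq.G_b)
        forcing = InsulinForcing(dtraj.times, dtraj.I)
        p = arch.minimal
        init = SystemState(2 * p.G_b, 0.0, 300.0)
        traj = simulate_minimal(p, forcing, init, output_times=[10.0, 60.0, 180.0],
                                t_end=180.0)
        ts, Y = rk4_minimal(p, init.as_array(), forcing, 180.0, h=0.002)
        for j, t in enumerate((10.0, 60.0, 180.0)):
            i = int(round(t / 0.002))
            for col, arr in enumerate((traj.G, traj.I, traj.F)):
                assert arr[j] == pytest.approx(Y[i, col], rel=1e-4, abs=1e-6)
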