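import numpy as np
import pytest
from dataclasses import replace

from glifa import delay_independent_stability, solve_steady_state
from glifa.stability import (
    characteristic_coefficients,
    jacobian_no_delay,
    p_coefficients,
    routh_hurwitz_no_delay,
)

from conftest import ALL_GROUPS, constructed_params
from oracles import numerical_jacobian


class TestCharacteristicCoefficients:
    def test_symmetric_point_closed_form(self):
        """With gamma = 1, sigma1 = 1, alpha = 1 and equilibrium glucose at
        the half-saturation point G_b = 1, the glucose-secretion
        sensitivity is exactly -1/4."""
        p = constructed_params(G_b=1.0, I_b=2.0, F_b=3.0, sigma1=1.0,
                               alpha=1.0, gamma=1.0, sigma=3.0, beta=2.0,
                               sigma2=0.5, g0=1.0, g1=2.0, I2=2.0, kappa=2.0,
                               S_i=0.01, S_g=0.1)
        eq = solve_steady_state(p)
        assert eq.G_b == pytest.approx(1.0, rel=1e-8)
        c = characteristic_coefficients(p, eq)
        assert c.A_hat == pytest.approx(-0.25, rel=1e-8)

    def test_no_ffa_secretion_decouples_b3(self, constructed):
        p = replace(constructed, sigma2=0.0)
        eq = solve_steady_state(p)
        c = characteristic_coefficients(p, eq)
        assert c.B_hat == 0.0
        assert c.b3 == pytest.approx(p.d_i * p.d_f, rel=1e-14)

    @pytest.mark.parametrize("group", ALL_GROUPS)
    def test_sensitivities_match_numerical_jacobian(self, archetypes, group):
        """Ahat, Bhat, Chat are (signed) entries of the equilibrium
        Jacobian; complex-step differentiation of the vector field
        recovers them."""
        p = archetypes[group].delay
        eq = solve_steady_state(p)
        c = characteristic_coefficients(p, eq)
        J = numerical_jacobian(p, eq)
        assert J[1, 0] == pytest.approx(-c.A_hat, rel=1e-6)
        assert J[1, 2] == pytest.approx(-c.B_hat, rel=1e-6, abs=1e-12)
        assert J[2, 1] == pytest.approx(-c.C_hat, rel=1e-6)
        # sign structure
        assert c.A_hat < 0 and c.B_hat <= 0 and c.C_hat >= 0 and c.b4 < 0

    def test_refuses_non_equilibrium_input(self, constructed):
        from glifa.steady_state import BasalState

        fake = BasalState(G_b=50.0, I_b=5.0, F_b=100.0, residual_norm=0.0)
        with pytest.raises(ValueError):
            characteristic_coefficients(constructed, fake)


class TestRouthHurwitz:
    @pytest.mark.parametrize(
        "b, d_f, expected",
        [
            ((1.0, 1.0, 1.0, 0.0), 1.0, True),    # (2)(2) = 4 > 1
            ((1.0, 1.0, 0.0, 10.0), 1.0, False),  # (2)(-9) = -18 < -10
        ],
    )
    def test_direct_arithmetic(self, b, d_f, expected):
        assert routh_hurwitz_no_delay(*b, d_f) is expected

    @pytest.mark.parametrize("group", ALL_GROUPS)
    def test_fixtures_stable_and_agree_with_eigenvalues(self, archetypes, group):
        p = archetypes[group].delay
        eq = solve_steady_state(p)
        c = characteristic_coefficients(p, eq)
        verdict = routh_hurwitz_no_delay(c.b1, c.b2, c.b3, c.b4, p.d_f)
        assert verdict is True
        lam = np.linalg.eigvals(jacobian_no_delay(p, eq))
        assert np.max(lam.real) < 0
        # analytic Jacobian itself agrees with the complex-step oracle
        J_num = numerical_jacobian(p, eq)
        assert np.allclose(jacobian_no_delay(p, eq), J_num, rtol=1e-6, atol=1e-12)


class TestPCoefficients:
    def test_direct_arithmetic(self):
        c2, c1, c0 = p_coefficients(1.0, 2.0, 3.0, 0.0, 1.0)
        assert (c2, c1, c0) == (-1.0, 7.0, 9.0)

    def test_algebraic_identities_on_random_tuples(self):
        rng = np.random.default_rng(12345)
        for _ in range(1000):
            b1, b2, b3, b4, d_f = rng.uniform(-5, 5, size=5)
            c2, c1, c0 = p_coefficients(b1, b2, b3, b4, d_f)
            assert c2 == pytest.approx((b1 + b2) ** 2 - 2 * (b1 * b2 + b3), rel=1e-12, abs=1e-12)
            assert c1 == pytest.approx(
                (b1 * b2 + b3) ** 2 - 2 * b1 * b3 * (b1 + b2) - b4**2, rel=1e-12, abs=1e-12
            )
            assert c0 == pytest.approx((b1 * b3) ** 2 - (b4 * d_f) ** 2, rel=1e-12, abs=1e-12)


class TestDelayIndependentStability:
    @pytest.mark.parametrize("group", ALL_GROUPS)
    def test_all_archetypes_stable_for_every_delay(self, archetypes, group):
        rep = delay_independent_stability(archetypes[group].delay)
        assert rep.stable_no_delay
        assert rep.descartes_sufficient        # c2, c1, c0 all positive
        assert rep.positive_u_roots == ()
        assert rep.delay_independent_stable

    def test_mixed_sign_pattern_checked_against_cubic_oracle(self):
        """For coefficients (-1, 7, 9) the cubic factors as
        (u + 1)(u^2 - 2u + 9): no positive real root despite the negative
        c2. The root finder must agree with the companion-matrix oracle
        rather than with the naive Descartes sign count."""
        from glifa.stability import _positive_real_roots

        roots = _positive_real_roots(-1.0, 7.0, 9.0)
        for u in roots:
            assert u > 0
            assert u**3 - u**2 + 7 * u + 9 == pytest.approx(0.0, abs=1e-8)
        all_roots = np.roots([1.0, -1.0, 7.0, 9.0])
        n_pos = sum(1 for r in all_roots if abs(r.imag) < 1e-9 and r.real > 0)
        assert len(roots) == n_pos == 0

    def test_steep_secretion_at_half_saturation_destroys_delay_independence(self):
        """A steep glucose response centred at the basal level
        (G_b = alpha, large gamma) with strong insulin-mediated removal
        makes |b4 d_f| exceed b1 b3, so c0 < 0 and p(u) has a positive
        root u = omega^2 — a candidate delay-induced oscillation."""
        p = constructed_params(G_b=140.0, I_b=20.0, F_b=300.0, S_i=0.01,
                               S_g=0.001, sigma1=30.0, sigma2=1e-4,
                               alpha=140.0, gamma=6.0, sigma=300.0, beta=8.0,
                               g0=1.0, g1=80.0, I2=18.0, kappa=5.0)
        rep = delay_independent_stability(p)
        assert rep.c0 < 0
        assert len(rep.positive_u_roots) >= 1
        assert not rep.delay_independent_stable
        # cross-check each reported root against the cubic itself
        for u in rep.positive_u_roots:
            assert u**3 + rep.c2 * u**2 + rep.c1 * u + rep.c0 == pytest.approx(
                0.0, abs=1e-6 * max(1.0, abs(rep.c0))
            )
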