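"""Closed-form perturbation solutions: oracles, identities, series behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate

from capform import (
    assemble_fields,
    constant_profile,
    fourier_spectrum,
    make_bump_profile,
    quartic_coefficients,
    series_n,
    solve_phi,
    solve_w,
    solve_xi,
    stable_B,
    steady_state,
)
from capform.analytic import phi_bracket, series_deviation_envelope

LAM, BETA, MU, D_ETA, K, EPS = 20.0, 10.0, 5.0, 0.25, 0.1, 0.05


class TestFactorAndProtease:
    def test_w_initial_condition_is_theta(self, quartic, ygrid):
        np.testing.assert_allclose(solve_w(ygrid, 0.0, quartic, LAM), quartic(ygrid))

    def test_w_worked_value(self, quartic):
        # theta(0.5) = 30/16 = 1.875, so w = 1.875 e^-2 at t = 0.1
        assert solve_w(0.5, 0.1, quartic, LAM) == pytest.approx(
            1.875 * np.exp(-2.0), rel=1e-12
        )

    def test_w_decays_monotonically(self, quartic):
        t = np.linspace(0.0, 2.0, 50)
        w = solve_w(0.3, t, quartic, LAM)
        assert np.all(np.diff(w) < 0)
        assert w[-1] < 1e-10

    def test_xi_starts_at_zero_and_saturates(self, quartic, ygrid):
        np.testing.assert_allclose(solve_xi(ygrid, 0.0, quartic, LAM), 0.0)
        np.testing.assert_allclose(
            solve_xi(ygrid, 5.0, quartic, LAM), quartic(ygrid), atol=1e-10
        )

    @settings(derandomize=True, max_examples=50)
    @given(
        y=st.floats(0.0, 1.0),
        t=st.floats(0.0, 10.0),
    )
    def test_factor_plus_protease_is_conserved(self, y, t):
        """w + xi = theta identically: the factor is converted to protease
        one-for-one."""
        theta = make_bump_profile(2)
        total = solve_w(y, t, theta, LAM) + solve_xi(y, t, theta, LAM)
        assert total == pytest.approx(float(theta(y)), abs=1e-14)


class TestFibronectinPerturbation:
    def test_initial_condition_is_zero(self, quartic, ygrid):
        np.testing.assert_allclose(
            solve_phi(ygrid, 0.0, quartic, LAM, BETA, MU), 0.0, atol=1e-15
        )

    def test_long_time_limit(self, quartic, ygrid):
        # phi -> mu*theta/beta = 0.5*theta
        np.testing.assert_allclose(
            solve_phi(ygrid, 10.0, quartic, LAM, BETA, MU),
            0.5 * quartic(ygrid),
            atol=1e-12,
        )

    def test_closed_form_against_ode_oracle(self, quartic):
        """Integrate phi_t + beta*phi = mu*theta*(1 - e^(-lambda t))
        numerically and compare with the closed form at t = 0.2."""
        y = 0.5
        th = float(quartic(y))

        def rhs(t, phi):
            return MU * th * (1.0 - np.exp(-LAM * t)) - BETA * phi

        sol = integrate.solve_ivp(
            rhs, (0.0, 0.2), [0.0], rtol=1e-11, atol=1e-13, dense_output=True
        )
        for t in (0.05, 0.1, 0.2):
            assert float(sol.sol(t)[0]) == pytest.approx(
                float(solve_phi(y, t, quartic, LAM, BETA, MU)), abs=1e-8
            )

    def test_confluent_branch_matches_ode_oracle(self, quartic):
        """At beta = lambda the generic formula degenerates; the confluent
        limit must still solve the ODE."""
        lam = beta = 10.0
        y = 0.4
        th = float(quartic(y))

        def rhs(t, phi):
            return MU * th * (1.0 - np.exp(-lam * t)) - beta * phi

        sol = integrate.solve_ivp(rhs, (0.0, 0.3), [0.0], rtol=1e-11, atol=1e-13)
        assert float(sol.y[0, -1]) == pytest.approx(
            float(solve_phi(y, 0.3, quartic, lam, beta, MU)), abs=1e-8
        )

    def test_confluent_branch_is_continuous(self):
        # approaching the degeneracy from outside matches the confluent value
        t = 0.17
        near = phi_bracket(t, 10.0 * (1 + 1e-9), 10.0)
        exact = phi_bracket(t, 10.0, 10.0)
        assert near == pytest.approx(exact, rel=1e-6)

    def test_phi_nondecreasing_in_time(self, quartic):
        t = np.linspace(0.0, 3.0, 300)
        phi = solve_phi(0.25, t, quartic, LAM, BETA, MU)
        assert np.all(np.diff(phi) >= -1e-14)


class TestFourierSpectrum:
    def test_c0_is_minus_2K_for_unit_mass(self, example_spectrum):
        assert example_spectrum.coefficients[0] == pytest.approx(-2 * K, abs=1e-12)

    def test_quadrature_matches_closed_form(self, example_spectrum):
        """Quadrature C_n vs the closed form 1440K/(n^4 pi^4) (even n),
        0 (odd n), up to n = 50."""
        closed = quartic_coefficients(50, K)
        np.testing.assert_allclose(
            example_spectrum.coefficients[:51], closed, atol=1e-9
        )

    def test_n2_value(self, example_spectrum):
        assert example_spectrum.coefficients[2] == pytest.approx(
            9.0 / np.pi**4, rel=1e-10
        )

    def test_odd_coefficients_vanish(self, example_spectrum):
        odd = example_spectrum.coefficients[1:51:2]
        assert np.max(np.abs(odd)) < 1e-10

    def test_constant_profile_has_no_oscillatory_content(self):
        spec = fourier_spectrum(constant_profile(), K, N=20)
        assert spec.coefficients[0] == pytest.approx(-2 * K)
        assert np.max(np.abs(spec.coefficients[1:])) < 1e-12

    def test_coefficients_bounded_by_profile_peak(self, example_spectrum, quartic):
        bound = 2 * K * float(quartic(0.5))
        assert np.max(np.abs(example_spectrum.coefficients)) <= bound + 1e-12

    def test_tail_bound_is_small_at_N200(self, example_spectrum):
        assert example_spectrum.tail_bound < 1e-6


class TestSeriesSolution:
    def test_initial_condition_vanishes(self, example_spectrum, quartic, ygrid):
        n0 = series_n(ygrid, 0.0, example_spectrum, quartic, D_ETA)
        assert np.max(np.abs(n0)) < 1e-6

    def test_long_time_limit(self, example_spectrum, quartic, ygrid):
        n_inf = series_n(ygrid, 50.0, example_spectrum, quartic, D_ETA)
        np.testing.assert_allclose(
            n_inf, -K + K * quartic(ygrid), atol=1e-12
        )

    def test_neumann_boundaries(self, example_spectrum, quartic):
        h = 1e-6
        for t in (0.05, 0.5):
            left = (
                series_n(h, t, example_spectrum, quartic, D_ETA)
                - series_n(0.0, t, example_spectrum, quartic, D_ETA)
            ) / h
            right = (
                series_n(1.0, t, example_spectrum, quartic, D_ETA)
                - series_n(1.0 - h, t, example_spectrum, quartic, D_ETA)
            ) / h
            assert abs(left) < 1e-4 and abs(right) < 1e-4

    @pytest.mark.parametrize("t", [0.01, 0.1, 1.0, 10.0])
    def test_zero_mean_at_all_times(self, example_spectrum, quartic, t):
        """Total cell perturbation is conserved at zero: C0/2 + K*mass
        cancels and cosines integrate to zero."""
        val, _ = integrate.quad(
            lambda y: float(series_n(y, t, example_spectrum, quartic, D_ETA)),
            0.0,
            1.0,
            epsabs=1e-11,
            limit=200,
        )
        assert abs(val) < 1e-8

    def test_heat_equation_residual(self, example_spectrum, quartic):
        """The substituted field u = n - K*theta solves u_t = D u_yy; check
        the truncated series by finite differences on interior points."""
        y = np.linspace(0.1, 0.9, 17)
        dt, dy = 1e-5, 1e-4

        def u(yy, tt):
            return series_n(
                yy, tt, example_spectrum, quartic, D_ETA
            ) - K * quartic(yy)

        for t in (0.05, 0.5):
            ut = (u(y, t + dt) - u(y, t - dt)) / (2 * dt)
            uyy = (u(y + dy, t) - 2 * u(y, t) + u(y - dy, t)) / dy**2
            assert np.max(np.abs(ut - D_ETA * uyy)) < 1e-4

    def test_exponential_envelope(self, example_spectrum, quartic, ygrid):
        """|n(y,t) - n_inf(y)| is dominated by the slowest surviving mode
        |C2| e^(-4 pi^2 D t) (with a small tail allowance)."""
        n_inf = -K + K * quartic(ygrid)
        C2 = example_spectrum.coefficients[2]
        for t in (0.05, 0.2, 0.5, 1.0):
            dev = np.max(
                np.abs(series_n(ygrid, t, example_spectrum, quartic, D_ETA) - n_inf)
            )
            assert dev <= 1.1 * abs(C2) * np.exp(-4 * np.pi**2 * D_ETA * t)

    def test_envelope_helper_bounds_deviation(self, example_spectrum, quartic, ygrid):
        n_inf = -K + K * quartic(ygrid)
        for t in (0.05, 0.3):
            dev = np.max(
                np.abs(series_n(ygrid, t, example_spectrum, quartic, D_ETA) - n_inf)
            )
            assert dev <= float(series_deviation_envelope(example_spectrum, D_ETA, t))

    def test_profile_mismatch_rejected(self, example_spectrum):
        with pytest.raises(ValueError, match="profile"):
            series_n(0.5, 0.1, example_spectrum, make_bump_profile(3), D_ETA)


class TestAssembledFields:
    def test_initial_data(self, example, ygrid):
        fields = assemble_fields(ygrid, 0.0, example.config, example.params)
        np.testing.assert_allclose(fields.v, EPS * example.config.theta(ygrid))
        np.testing.assert_allclose(fields.c, 0.0, atol=1e-15)
        np.testing.assert_allclose(fields.f, 1.0, atol=1e-15)
        np.testing.assert_allclose(fields.eta, 1.0, atol=1e-6)

    def test_worked_value_for_factor_density(self, example):
        fields = assemble_fields(0.5, 0.1, example.config, example.params)
        assert float(fields.v) == pytest.approx(0.05 * 1.875 * np.exp(-2.0), rel=1e-12)
        assert float(fields.v) == pytest.approx(0.012688, abs=5e-7)

    @pytest.mark.parametrize("t", [0.0, 0.03, 0.1, 1.0])
    def test_factor_protease_sum_identity(self, example, ygrid, t):
        fields = assemble_fields(ygrid, t, example.config, example.params)
        np.testing.assert_allclose(
            fields.v + fields.c, EPS * example.config.theta(ygrid), atol=1e-14
        )

    def test_fibronectin_stays_in_unit_interval(self, example, ygrid):
        for t in (0.0, 0.1, 1.0, 10.0):
            fields = assemble_fields(ygrid, t, example.config, example.params)
            assert np.all(fields.f > 0.0)
            assert np.all(fields.f <= 1.0 + 1e-15)

    def test_perturbation_regime_violation_warns(self, example, ygrid):
        import dataclasses

        big = dataclasses.replace(example.config, epsilon=5.0)
        with pytest.warns(UserWarning, match="perturbation regime"):
            assemble_fields(ygrid, 1.0, big, example.params)


class TestSteadyState:
    def test_stable_constant_is_minus_K(self, example_spectrum):
        assert stable_B(example_spectrum, K) == pytest.approx(-0.1, abs=1e-12)

    def test_stable_B_independent_of_profile_shape(self):
        for theta in (make_bump_profile(3), constant_profile()):
            spec = fourier_spectrum(theta, K, N=10)
            assert stable_B(spec, K) == pytest.approx(-K, abs=1e-12)

    def test_steady_state_matches_long_time_series(
        self, example_spectrum, quartic, ygrid
    ):
        B = stable_B(example_spectrum, K)
        n_ss = steady_state(ygrid, B, K, quartic)
        n_late = series_n(ygrid, 50.0, example_spectrum, quartic, D_ETA)
        np.testing.assert_allclose(n_late, n_ss, atol=1e-12)

    def test_zero_K_gives_flat_state(self, quartic):
        np.testing.assert_allclose(
            steady_state(np.linspace(0, 1, 11), 0.7, 0.0, quartic), 0.7
        )

    def test_vanishes_at_walls_when_B_zero(self, quartic):
        assert steady_state(0.0, 0.0, K, quartic) == 0.0
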