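"""Neimark-Sacker normal-form reduction: Taylor coefficients, the
conjugating transform, xi coefficients, and the first Lyapunov quantity."""

import cmath

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ppmap.model import ModelParams, interior_equilibrium, jacobian
from ppmap.normal_form import (
    NotOnCriticalLocusError,
    conjugate_to_rotation,
    eta_zeta,
    omega,
    taylor_coeffs,
    third_order_partials,
    translated_map,
    xi21_from_map,
    xi_coefficients,
    xi_from_partials,
)
from ppmap.stability import ns_critical_alpha

from conftest import ALPHA_CRIT_REF, fd_quadratic_coeffs, random_HA_params


class TestTaylorCoeffs:
    def test_reference_values_at_critical(self, params_critical):
        tc = taylor_coeffs(params_critical)
        assert tc.a11 == pytest.approx(0.574074, abs=1e-6)
        assert tc.a12 == pytest.approx(-0.23)
        assert tc.a13 == pytest.approx(-1.851852, abs=1e-6)
        assert tc.a14 == -1.0
        assert tc.a21 == pytest.approx(1.851852, abs=1e-6)
        assert tc.a22 == 1.0
        assert tc.a23 == pytest.approx(4.347826, abs=1e-6)

    def test_a14_and_a22_are_parameter_independent(self, rng):
        for p in random_HA_params(rng, 10):
            tc = taylor_coeffs(p)
            assert tc.a14 == -1.0
            assert tc.a22 == 1.0

    def test_off_critical_requires_force(self, params_stable):
        with pytest.raises(NotOnCriticalLocusError):
            taylor_coeffs(params_stable)
        tc = taylor_coeffs(params_stable, force=True)
        assert tc.a13 == pytest.approx(-1.48)

    def test_all_coeffs_match_finite_differences_of_translated_map(self, rng):
        """The closed forms must be the actual Taylor expansion of the
        translated map (10 random critical points, tol 1e-5)."""
        for p in random_HA_params(rng, 10):
            tc = taylor_coeffs(p)
            f = translated_map(p)
            cu = fd_quadratic_coeffs(lambda u, v: f(u, v)[0])
            cv = fd_quadratic_coeffs(lambda u, v: f(u, v)[1])
            assert cu["u"] == pytest.approx(tc.a11, abs=1e-5)
            assert cu["v"] == pytest.approx(tc.a12, abs=1e-5)
            assert cu["uu"] == pytest.approx(tc.a13, abs=1e-5)
            assert cu["uv"] == pytest.approx(tc.a14, abs=1e-5)
            assert cu["vv"] == pytest.approx(0.0, abs=1e-5)
            assert cv["u"] == pytest.approx(tc.a21, abs=1e-5)
            assert cv["v"] == pytest.approx(tc.a22, abs=1e-5)
            assert cv["uu"] == pytest.approx(0.0, abs=1e-5)
            assert cv["uv"] == pytest.approx(tc.a23, abs=1e-5)


class TestEtaZeta:
    def test_jacobian_convention_is_re_lambda(self, params_critical):
        eta, zeta = eta_zeta(params_critical, "jacobian")
        assert eta == pytest.approx(0.787037, abs=1e-6)
        assert zeta == pytest.approx(0.616906, abs=1e-6)

    def test_paper_convention_flips_sign_of_eta(self, params_critical):
        eta_j, zeta_j = eta_zeta(params_critical, "jacobian")
        eta_p, zeta_p = eta_zeta(params_critical, "paper")
        assert eta_p == pytest.approx(-eta_j)
        assert zeta_p == zeta_j

    def test_unit_modulus_on_critical_locus(self, rng):
        for p in random_HA_params(rng, 10):
            for conv in ("jacobian", "paper"):
                eta, zeta = eta_zeta(p, conv)
                assert eta * eta + zeta * zeta == pytest.approx(1.0, abs=1e-8)

    def test_domain_error_when_delta_nonnegative(self):
        with pytest.raises(ValueError):
            eta_zeta(ModelParams(1.2, 0.9))


class TestConjugation:
    def test_rotation_conjugacy_at_random_critical_points(self, rng):
        """With eta = Re(lambda), T^-1 J(A) T must be exactly the
        rotation-scaling matrix [[eta, -zeta], [zeta, eta]]."""
        for p in random_HA_params(rng, 20):
            tc = taylor_coeffs(p)
            eta, zeta = eta_zeta(p, "jacobian")
            T, *_ = conjugate_to_rotation(tc, eta, zeta)
            J = jacobian(interior_equilibrium(p), p)
            R = np.linalg.solve(T, J @ T)
            target = np.array([[eta, -zeta], [zeta, eta]])
            assert np.max(np.abs(R - target)) <= 1e-8

    def test_derived_c_coefficients_match_finite_differences(self, rng):
        """(c11, c12, c21, c22) must be the actual quadratic part of
        T^-1 o (translated map) o T."""
        for p in random_HA_params(rng, 10):
            tc = taylor_coeffs(p)
            eta, zeta = eta_zeta(p, "jacobian")
            T, c11, c12, c21, c22 = conjugate_to_rotation(tc, eta, zeta)
            f = translated_map(p)
            Tinv = np.linalg.inv(T)

            def composed(X, Y):
                u, v = T @ np.array([X, Y])
                return Tinv @ np.array(f(u, v))

            cF = fd_quadratic_coeffs(lambda X, Y: composed(X, Y)[0])
            cG = fd_quadratic_coeffs(lambda X, Y: composed(X, Y)[1])
            assert cF["uu"] == pytest.approx(c11, abs=1e-5)
            assert cF["uv"] == pytest.approx(c12, abs=1e-5)
            assert cF["vv"] == pytest.approx(0.0, abs=1e-5)
            assert cG["uu"] == pytest.approx(c21, abs=1e-5)
            assert cG["uv"] == pytest.approx(c22, abs=1e-5)
            assert cG["vv"] == pytest.approx(0.0, abs=1e-5)
            # and the linear part really is the rotation
            assert cF["u"] == pytest.approx(eta, abs=1e-8)
            assert cF["v"] == pytest.approx(-zeta, abs=1e-8)
            assert cG["u"] == pytest.approx(zeta, abs=1e-8)
            assert cG["v"] == pytest.approx(eta, abs=1e-8)

    def test_paper_convention_reproduces_printed_forms(self, params_critical):
        tc = taylor_coeffs(params_critical)
        eta, zeta = eta_zeta(params_critical, "jacobian")
        _, c11, c12, c21, c22 = conjugate_to_rotation(
            tc, eta, zeta, c_convention="paper"
        )
        k = eta - tc.a11
        assert c12 == -zeta
        assert c11 == pytest.approx(tc.a12 * tc.a13 + k * tc.a14)
        assert c22 == pytest.approx((tc.a23 - k * tc.a14 / tc.a12) * tc.a12)

    def test_singular_transform_rejected(self, params_critical):
        tc = taylor_coeffs(params_critical)
        eta, _ = eta_zeta(params_critical)
        with pytest.raises(ValueError):
            conjugate_to_rotation(tc, eta, 0.0)


class TestXiCoefficients:
    def test_xi21_is_identically_zero(self, rng):
        for _ in range(20):
            c = rng.uniform(-5, 5, size=4)
            assert xi_coefficients(*c)[3] == 0

    def test_zero_quadratic_part_gives_all_zero(self):
        assert xi_coefficients(0.0, 0.0, 0.0, 0.0) == (0j, 0j, 0j, 0j)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.tuples(*[st.floats(-10, 10) for _ in range(4)]))
    def test_closed_forms_agree_with_derivative_definitions(self, c):
        """xi's from (c11, c12, c21, c22) must equal the derivative-based
        route with Fxx = 2c11, Fxy = c12, Gxx = 2c21, Gxy = c22."""
        c11, c12, c21, c22 = c
        direct = xi_coefficients(c11, c12, c21, c22)
        via_partials = xi_from_partials(
            Fxx=2 * c11, Fxy=c12, Fyy=0.0,
            Gxx=2 * c21, Gxy=c22, Gyy=0.0,
        )
        for a, b in zip(direct, via_partials):
            assert a == pytest.approx(b, abs=1e-12)

    def test_third_order_partials_of_transformed_map_vanish(
        self, params_critical
    ):
        parts = third_order_partials(params_critical)
        assert all(v == 0.0 for v in parts.values())
        assert xi21_from_map(params_critical) == 0j


class TestOmega:
    def test_negative_at_reference_beta(self, params_critical):
        rep = omega(params_critical)
        assert rep.omega < 0
        assert rep.verdict == "supercritical-attracting"
        assert rep.eta_convention == "jacobian"

    def test_terms_sum_to_omega_and_xi21_term_vanishes(self, params_critical):
        rep = omega(params_critical)
        assert sum(rep.omega_terms.values()) == pytest.approx(rep.omega)
        assert rep.omega_terms["lam_xi21"] == 0.0
        assert rep.xi21 == 0j

    def test_both_conventions_reported(self, params_critical):
        rep = omega(params_critical)
        assert set(rep.omega_by_convention) == {"jacobian", "paper"}
        assert rep.omega_by_convention["jacobian"] == rep.omega

    @pytest.mark.parametrize("beta", [0.13, 0.23, 0.35])
    def test_supercritical_across_reference_betas(self, beta):
        p = ModelParams(ns_critical_alpha(beta), beta)
        assert omega(p).omega < 0

    def test_degenerate_verdict_when_omega_below_tolerance(
        self, params_critical
    ):
        rep = omega(params_critical, degeneracy_tol=1e3)
        assert rep.verdict == "degenerate"

    def test_off_critical_requires_force(self, params_stable):
        with pytest.raises(NotOnCriticalLocusError):
            omega(params_stable)
        rep = omega(params_stable, force=True)
        assert rep.zeta > 0

    def test_unit_modulus_invariant_in_report(self, rng):
        for p in random_HA_params(rng, 5):
            rep = omega(p)
            assert rep.eta**2 + rep.zeta**2 == pytest.approx(1.0, abs=1e-8)
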