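"""Neimark-Sacker normal-form reduction at the critical parameter.

Pipeline, all at a point (alpha_1, beta_1) on the critical locus H_A:

1. translate the interior equilibrium A to the origin (u = x - beta_1,
   v = y - alpha_1*(1-beta_1) + 1) and Taylor-expand; the map is quadratic,
   so the expansion

       u' = a11*u + a12*v + a13*u^2 + a14*u*v
       v' = a21*u + a22*v + a23*u*v

   is exact, with closed-form coefficients a_ij;
2. build the real conjugating transform T = [[a12, 0], [eta - a11, -zeta]]
   from the critical eigenvalue lambda = eta + i*zeta (|lambda| = 1), so the
   linear part becomes the rotation-scaling [[eta, -zeta], [zeta, eta]];
3. read off the quadratic part (c11, c12, c21, c22) of the transformed map
   X' = eta*X - zeta*Y + F(X,Y), Y' = zeta*X + eta*Y + G(X,Y);
4. combine into the complex normal-form coefficients xi_02, xi_11, xi_20,
   xi_21 and evaluate the discriminatory (first Lyapunov) quantity

       Omega = -Re[(1-2*conj(lam))*conj(lam)^2 / (1-lam) * xi11*xi20]
               - |xi11|^2 / 2 - |xi02|^2 + Re(conj(lam)*xi21).

Omega < 0: an attracting invariant closed curve bifurcates as the
perturbation alpha* crosses 0 from below (supercritical); Omega > 0:
a repelling curve (subcritical); Omega = 0: degenerate, the criterion is
inconclusive.

Two deliberate convention switches are exposed (see docs/methods.md):

``convention`` — the sign of eta.  The source derivation prints
eta = (alpha_1*beta_1 - 2)/2, the negative of Re(lambda); only
eta = Re(lambda) = (2 - alpha_1*beta_1)/2 makes T^-1 J(A) T the
rotation-scaling matrix the normal form assumes, so "jacobian" is the
default and "paper" is retained for literal reproduction.

``c_convention`` — the quadratic coefficients.  "derived" (default) uses
the actual quadratic part of the conjugated map, verified against finite
differences; "paper" uses the printed closed forms, which differ in c12
(sign, via the a14 factor) and in c21 (an extra a12 factor).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .model import ModelParams, State, interior_equilibrium, jacobian
from .stability import membership_HA

__all__ = [
    "TaylorCoeffs",
    "NormalFormReport",
    "taylor_coeffs",
    "translated_map",
    "eta_zeta",
    "conjugate_to_rotation",
    "xi_coefficients",
    "xi_from_partials",
    "third_order_partials",
    "xi21_from_map",
    "omega",
]

Convention = Literal["jacobian", "paper"]
CConvention = Literal["derived", "paper"]

#: |Omega| at or below this reports "degenerate"
DEGENERACY_TOL = 1e-10


class NotOnCriticalLocusError(ValueError):
    """The parameters are not on H_A (pass force=True to override)."""


@dataclass(frozen=True)
class TaylorCoeffs:
    """Exact quadratic Taylor coefficients of the translated map.

    Closed forms: a11 = 1 - alpha*beta, a12 = -beta, a13 = -alpha,
    a14 = -1, a21 = (alpha*(1-beta) - 1)/beta, a22 = 1, a23 = 1/beta.
    """

    a11: float
    a12: float
    a13: float
    a14: float
    a21: float
    a22: float
    a23: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in
                ("a11", "a12", "a13", "a14", "a21", "a22", "a23")}


@dataclass(frozen=True)
class NormalFormReport:
    """Every intermediate of the reduction plus the criticality verdict."""

    params: ModelParams
    eta: float
    zeta: float
    T: np.ndarray
    taylor: TaylorCoeffs
    c11: float
    c12: float
    c21: float
    c22: float
    xi02: complex
    xi11: complex
    xi20: complex
    xi21: complex
    omega: float
    omega_terms: dict[str, float]
    omega_by_convention: dict[str, float]
    verdict: str
    eta_convention: str
    c_convention: str

    def to_dict(self) -> dict:
        cplx = lambda z: {"re": z.real, "im": z.imag}
        return {
            "alpha": self.params.alpha,
            "beta": self.params.beta,
            "eta": self.eta,
            "zeta": self.zeta,
            "T": [list(row) for row in self.T.tolist()],
            "taylor": self.taylor.as_dict(),
            "c11": self.c11,
            "c12": self.c12,
            "c21": self.c21,
            "c22": self.c22,
            "xi02": cplx(self.xi02),
            "xi11": cplx(self.xi11),
            "xi20": cplx(self.xi20),
            "xi21": cplx(self.xi21),
            "omega": self.omega,
            "omega_terms": self.omega_terms,
            "omega_by_convention": self.omega_by_convention,
            "verdict": self.verdict,
            "eta_convention": self.eta_convention,
            "c_convention": self.c_convention,
        }


def _require_critical(params: ModelParams, force: bool) -> None:
    if force:
        return
    m = membership_HA(params, tol=1e-6)
    if not m.in_HA:
        raise NotOnCriticalLocusError(
            f"(alpha={params.alpha}, beta={params.beta}) is not on H_A "
            f"(critical alpha = {m.alpha_critical}); pass force=True to "
            f"evaluate off-critical"
        )


def translated_map(
    params: ModelParams, alpha_star: float = 0.0
) -> Callable[[float, float], tuple[float, float]]:
    """The map in coordinates centred on A, with perturbation alpha*.

    u = x - beta, v = y - (alpha*(1-beta) - 1); the fixed point A of the
    unperturbed map sits at the origin.  Used as the ground truth for
    finite-difference verification of the Taylor coefficients.
    """
    a1, b1 = params.alpha, params.beta
    ystar = a1 * (1.0 - b1) - 1.0
    a = a1 + alpha_star

    def f(u: float, v: float) -> tuple[float, float]:
        x = u + b1
        y = v + ystar
        return (a * x * (1.0 - x) - x * y - b1,
                (x * y) / b1 - ystar)

    return f


def taylor_coeffs(params: ModelParams, force: bool = False) -> TaylorCoeffs:
    """Closed-form Taylor coefficients of the translated map at alpha* = 0.

    Requires (alpha, beta) on H_A unless ``force`` — off-critical the
    coefficients are still exact for the translated map, but the normal
    form downstream is only meaningful at criticality.
    """
    _require_critical(params, force)
    a1, b1 = params.alpha, params.beta
    return TaylorCoeffs(
        a11=1.0 - a1 * b1,
        a12=-b1,
        a13=-a1,
        a14=-1.0,
        a21=(a1 * (1.0 - b1) - 1.0) / b1,
        a22=1.0,
        a23=1.0 / b1,
    )


def eta_zeta(
    params: ModelParams, convention: Convention = "jacobian"
) -> tuple[float, float]:
    """Real and imaginary parts of the critical eigenvalue.

    convention="jacobian": eta = (2 - alpha*beta)/2 = Re(lambda) from the
    actual Jacobian; convention="paper": eta = (alpha*beta - 2)/2, the
    printed form.  zeta = sqrt(4*alpha - (alpha*beta + 2)^2)/2 > 0 either
    way; requires Delta < 0.
    """
    a1, b1 = params.alpha, params.beta
    rad = 4.0 * a1 - (a1 * b1 + 2.0) ** 2  # = -Delta
    if rad <= 0.0:
        raise ValueError(
            f"Delta = {-rad} >= 0: eigenvalues are real, no rotation part"
        )
    zeta = 0.5 * math.sqrt(rad)
    if convention == "jacobian":
        eta = (2.0 - a1 * b1) / 2.0
    elif convention == "paper":
        eta = (a1 * b1 - 2.0) / 2.0
    else:
        raise ValueError(f"unknown eta convention: {convention!r}")
    return eta, zeta


def conjugate_to_rotation(
    tc: TaylorCoeffs,
    eta: float,
    zeta: float,
    c_convention: CConvention = "derived",
) -> tuple[np.ndarray, float, float, float, float]:
    """The conjugating transform T and the quadratic coefficients of the
    transformed map.

    T = [[a12, 0], [eta - a11, -zeta]].  With eta = Re(lambda),
    T^-1 J(A) T = [[eta, -zeta], [zeta, eta]] exactly.

    c_convention="derived" returns the true quadratic part of
    T^-1 o (translated map) o T:

        c11 = a12*a13 + k*a14
        c12 = -a14*zeta
        c21 = (k/zeta) * (a12*a13 + k*a14 - a12*a23)
        c22 = a12*a23 - k*a14           with k = eta - a11;

    c_convention="paper" returns the printed closed forms (c12 = -zeta and
    a c21 with an extra a12 factor on the a14 term), kept for literal
    reproduction.
    """
    if tc.a12 == 0.0 or zeta == 0.0:
        raise ValueError("transform singular: a12 = 0 or zeta = 0")
    k = eta - tc.a11
    T = np.array([[tc.a12, 0.0], [k, -zeta]], dtype=float)
    if c_convention == "derived":
        c11 = tc.a12 * tc.a13 + k * tc.a14
        c12 = -tc.a14 * zeta
        c21 = (k / zeta) * (tc.a12 * tc.a13 + k * tc.a14 - tc.a12 * tc.a23)
        c22 = tc.a12 * tc.a23 - k * tc.a14
    elif c_convention == "paper":
        c11 = tc.a12 * tc.a13 + k * tc.a14
        c12 = -zeta
        c21 = (1.0 / zeta) * (
            k * tc.a12 * tc.a13 + (k * tc.a14 - tc.a23) * k * tc.a12
        )
        c22 = (tc.a23 - k * tc.a14 / tc.a12) * tc.a12
    else:
        raise ValueError(f"unknown c convention: {c_convention!r}")
    return T, c11, c12, c21, c22


def xi_coefficients(
    c11: float, c12: float, c21: float, c22: float
) -> tuple[complex, complex, complex, complex]:
    """Complex normal-form coefficients from the quadratic part.

    xi02 = (c11 + c22 + i*(c21 + c12))/4
    xi11 = (c11 + i*c21)/2
    xi20 = (c11 + c22 + i*(c21 - c12))/4
    xi21 = 0   (the map is quadratic: all third-order partials vanish)
    """
    xi02 = complex(c11 + c22, c21 + c12) / 4.0
    xi11 = complex(c11, c21) / 2.0
    xi20 = complex(c11 + c22, c21 - c12) / 4.0
    xi21 = complex(0.0, 0.0)
    return xi02, xi11, xi20, xi21


def xi_from_partials(
    Fxx: float, Fxy: float, Fyy: float,
    Gxx: float, Gxy: float, Gyy: float,
    Fxxx: float = 0.0, Fxxy: float = 0.0, Fxyy: float = 0.0, Fyyy: float = 0.0,
    Gxxx: float = 0.0, Gxxy: float = 0.0, Gxyy: float = 0.0, Gyyy: float = 0.0,
) -> tuple[complex, complex, complex, complex]:
    """The derivative-based definitions of the xi coefficients.

    Independent route used to cross-check :func:`xi_coefficients`: with
    Fxx = 2*c11, Fxy = c12, Fyy = 0, Gxx = 2*c21, Gxy = c22, Gyy = 0 and
    vanishing third partials, the two routes agree identically.
    """
    xi02 = (complex(Fxx - Fyy + 2.0 * Gxy, Gxx - Gyy + 2.0 * Fxy)) / 8.0
    xi11 = (complex(Fxx + Fyy, Gxx + Gyy)) / 4.0
    xi20 = (complex(Fxx - Fyy + 2.0 * Gxy, Gxx - Gyy - 2.0 * Fxy)) / 8.0
    xi21 = (
        complex(Fxxx + Fxyy + Gxxy + Gyyy, Gxxx + Gxyy - Fxxy - Fyyy)
    ) / 16.0
    return xi02, xi11, xi20, xi21


def third_order_partials(
    params: ModelParams,
    convention: Convention = "jacobian",
    force: bool = False,
) -> dict[str, float]:
    """All eight third-order partials of (F, G) at the origin, computed by
    exact symbolic differentiation of the fully composed transformed map.

    This is an evaluation, not an appeal to the quadratic structure: the
    translated map is composed with T and T^-1 symbolically (sympy) and
    differentiated three times.  Every partial comes out exactly zero, which
    is what forces xi21 = 0.
    """
    import sympy as sp

    _require_critical(params, force)
    a1 = sp.Rational(params.alpha).limit_denominator(10**12)
    b1 = sp.Rational(params.beta).limit_denominator(10**12)
    X, Y = sp.symbols("X Y", real=True)
    ystar = a1 * (1 - b1) - 1
    a11 = 1 - a1 * b1
    a12 = -b1
    zeta = sp.sqrt(4 * a1 - (a1 * b1 + 2) ** 2) / 2
    eta = (a1 * b1 - 2) / 2 if convention == "paper" else (2 - a1 * b1) / 2
    k = eta - a11
    # (u, v) = T (X, Y)
    u = a12 * X
    v = k * X - zeta * Y
    x = u + b1
    y = v + ystar
    u1 = a1 * x * (1 - x) - x * y - b1
    v1 = x * y / b1 - ystar
    # (X', Y') = T^-1 (u1, v1)
    X1 = u1 / a12
    Y1 = (k * u1 / a12 - v1) / zeta
    F = sp.expand(X1 - (eta * X - zeta * Y))
    G = sp.expand(Y1 - (zeta * X + eta * Y))
    out: dict[str, float] = {}
    for name, expr in (("F", F), ("G", G)):
        for orders, tag in (((3, 0), "xxx"), ((2, 1), "xxy"),
                            ((1, 2), "xyy"), ((0, 3), "yyy")):
            d = sp.diff(expr, X, orders[0], Y, orders[1])
            out[f"{name}{tag}"] = float(d.subs({X: 0, Y: 0}))
    return out


def xi21_from_map(
    params: ModelParams,
    convention: Convention = "jacobian",
    force: bool = False,
) -> complex:
    """xi21 assembled from symbolically evaluated third-order partials."""
    p = third_order_partials(params, convention, force)
    return complex(
        p["Fxxx"] + p["Fxyy"] + p["Gxxy"] + p["Gyyy"],
        p["Gxxx"] + p["Gxyy"] - p["Fxxy"] - p["Fyyy"],
    ) / 16.0


def omega(
    params: ModelParams,
    convention: Convention = "jacobian",
    c_convention: CConvention = "derived",
    force: bool = False,
    degeneracy_tol: float = DEGENERACY_TOL,
) -> NormalFormReport:
    """Full normal-form reduction and the first Lyapunov quantity Omega.

    The report carries every intermediate, a term-by-term breakdown of
    Omega, the value under the alternative eta convention (for comparison),
    and the criticality verdict: Omega < 0 supercritical-attracting,
    Omega > 0 subcritical-repelling, |Omega| <= degeneracy_tol degenerate.
    """
    _require_critical(params, force)
    tc = taylor_coeffs(params, force=True)
    eta, zeta = eta_zeta(params, convention)
    T, c11, c12, c21, c22 = conjugate_to_rotation(tc, eta, zeta, c_convention)
    xi02, xi11, xi20, xi21 = xi_coefficients(c11, c12, c21, c22)
    lam = complex(eta, zeta)
    if abs(1.0 - lam) < 1e-12:
        raise ValueError("lambda = 1: strong 1:1 resonance, Omega undefined")
    lb = lam.conjugate()
    term1 = -((1.0 - 2.0 * lb) * lb**2 / (1.0 - lam) * xi11 * xi20).real
    term2 = -0.5 * abs(xi11) ** 2
    term3 = -abs(xi02) ** 2
    term4 = (lb * xi21).real
    om = term1 + term2 + term3 + term4

    other: Convention = "paper" if convention == "jacobian" else "jacobian"
    eo, zo = eta_zeta(params, other)
    _, d11, d12, d21, d22 = conjugate_to_rotation(tc, eo, zo, c_convention)
    o02, o11, o20, o21 = xi_coefficients(d11, d12, d21, d22)
    lo = complex(eo, zo)
    om_other = (
        -(((1.0 - 2.0 * lo.conjugate()) * lo.conjugate() ** 2 / (1.0 - lo))
          * o11 * o20).real
        - 0.5 * abs(o11) ** 2 - abs(o02) ** 2 + (lo.conjugate() * o21).real
    )

    if abs(om) <= degeneracy_tol:
        verdict = "degenerate"
    elif om < 0.0:
        verdict = "supercritical-attracting"
    else:
        verdict = "subcritical-repelling"

    return NormalFormReport(
        params=params,
        eta=eta,
        zeta=zeta,
        T=T,
        taylor=tc,
        c11=c11, c12=c12, c21=c21, c22=c22,
        xi02=xi02, xi11=xi11, xi20=xi20, xi21=xi21,
        omega=om,
        omega_terms={
            "prefactor_term": term1,
            "half_xi11_sq": term2,
            "xi02_sq": term3,
            "lam_xi21": term4,
        },
        omega_by_convention={convention: om, other: om_other},
        verdict=verdict,
        eta_convention=convention,
        c_convention=c_convention,
    )
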