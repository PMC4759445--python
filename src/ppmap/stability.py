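"""Topological classification of the fixed points and the
Neimark-Sacker preconditions.

The origin O is a sink for alpha < 1, a saddle for alpha > 1, and
non-hyperbolic at alpha = 1 (its eigenvalues are {alpha, 0}).  The interior
equilibrium A = (beta, alpha*(1-beta)-1) is classified by a case table on
(Delta, alpha):

    sink    if (Delta >= 0 and alpha < 1/(1-beta))
            or (Delta <  0 and alpha < 1/(1-2*beta))
    source  if (Delta >= 0 and alpha > 1/(1-beta))
            or (Delta <  0 and alpha > 1/(1-2*beta))
    non-hyperbolic on the respective equalities.

On the locus H_A = {Delta < 0, alpha = 1/(1-2*beta), beta < 1/2} the
eigenvalues of J(A) are a complex-conjugate pair of modulus exactly one:
the Neimark-Sacker candidate.  Because the case table is known to disagree
with the raw eigenvalue moduli in part of parameter space (the Delta >= 0,
q < 0 region is a saddle, not a source), ``classify_interior`` reports both
the table verdict and an eigenvalue-derived verdict with a consistency
flag, rather than silently trusting either.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .model import (
    CharCoeffs,
    ModelParams,
    State,
    char_coeffs,
    eigenvalues_at,
    interior_equilibrium,
    interior_exists,
)

__all__ = [
    "EquilibriumReport",
    "HAMembership",
    "NonresonanceResult",
    "NoEquilibriumError",
    "classify_origin",
    "classify_interior",
    "ns_critical_alpha",
    "transversality",
    "nonresonance_check",
    "membership_HA",
]

#: default tolerance for "alpha equals a threshold" decisions
EQUALITY_TOL = 1e-9
#: default tolerance for the nonresonance distances |lambda^k - 1|
NONRESONANCE_TOL = 1e-8


class NoEquilibriumError(ValueError):
    """The interior equilibrium does not exist at these parameters."""


@dataclass(frozen=True)
class EquilibriumReport:
    """Classification record for one equilibrium.

    ``classification`` is the lemma-table verdict; ``eigen_classification``
    is recomputed from raw eigenvalue moduli, and ``consistent`` flags
    whether the two agree (hyperbolic cases).  ``ns_candidate`` is true
    only for a non-hyperbolic interior equilibrium with Delta < 0 that also
    passes the nonresonance check.
    """

    label: str
    location: State
    char: CharCoeffs
    eigenvalues: tuple[complex, complex]
    classification: str
    ns_candidate: bool = False
    eigen_classification: str | None = None
    consistent: bool | None = None
    notes: str = ""

    def to_dict(self) -> dict:
        lam1, lam2 = self.eigenvalues
        return {
            "label": self.label,
            "location": {"x": self.location.x, "y": self.location.y},
            "char": {"p": self.char.p, "q": self.char.q, "delta": self.char.delta},
            "eigenvalues": [
                {"re": lam1.real, "im": lam1.imag, "abs": abs(lam1)},
                {"re": lam2.real, "im": lam2.imag, "abs": abs(lam2)},
            ],
            "classification": self.classification,
            "ns_candidate": self.ns_candidate,
            "eigen_classification": self.eigen_classification,
            "consistent": self.consistent,
            "notes": self.notes,
        }


@dataclass(frozen=True)
class HAMembership:
    """Membership of (alpha, beta) in the non-hyperbolic NS locus H_A."""

    in_HA: bool
    alpha_critical: float | None
    distance: float | None

    def to_dict(self) -> dict:
        return {
            "in_HA": self.in_HA,
            "alpha_critical": self.alpha_critical,
            "distance": self.distance,
        }


@dataclass(frozen=True)
class NonresonanceResult:
    """Outcome of the strong-resonance exclusion lambda^k != 1, k = 1..4."""

    passed: bool
    distances: tuple[float, float, float, float]
    lam: complex

    def __bool__(self) -> bool:
        return self.passed


def _eigen_verdict(lams: tuple[complex, complex], tol: float) -> str:
    mods = sorted(abs(l) for l in lams)
    if any(abs(m - 1.0) <= tol for m in mods):
        return "non-hyperbolic"
    if mods[1] < 1.0:
        return "sink"
    if mods[0] > 1.0:
        return "source"
    return "saddle"


def classify_origin(
    params: ModelParams, tol: float = EQUALITY_TOL
) -> EquilibriumReport:
    """Classify O(0, 0): sink for alpha < 1, saddle for alpha > 1,
    non-hyperbolic at alpha = 1."""
    a = params.alpha
    O = State(0.0, 0.0)
    lams = eigenvalues_at(O, params)  # {alpha, 0}
    if abs(a - 1.0) <= tol:
        verdict = "non-hyperbolic"
    elif a < 1.0:
        verdict = "sink"
    else:
        verdict = "saddle"
    # p, q of the characteristic polynomial of J(O) = diag(alpha, 0)
    char = CharCoeffs(p=a, q=0.0, delta=a * a)
    eig_verdict = _eigen_verdict(lams, tol)
    return EquilibriumReport(
        label="O",
        location=O,
        char=char,
        eigenvalues=lams,
        classification=verdict,
        ns_candidate=False,
        eigen_classification=eig_verdict,
        consistent=(verdict == eig_verdict),
    )


def classify_interior(
    params: ModelParams, tol: float = EQUALITY_TOL
) -> EquilibriumReport:
    """Classify the interior equilibrium A by the (Delta, alpha) case table,
    cross-checked against eigenvalue moduli.

    Raises :class:`NoEquilibriumError` when A does not exist
    (beta >= 1 or alpha <= 1/(1-beta)).
    """
    a, b = params.alpha, params.beta
    if not interior_exists(params):
        raise NoEquilibriumError(
            f"interior equilibrium absent: need beta < 1 and "
            f"alpha > 1/(1-beta); got alpha={a}, beta={b}"
        )
    A = interior_equilibrium(params)
    char = char_coeffs(params)
    lams = eigenvalues_at(A, params)

    thr_real = 1.0 / (1.0 - b)  # Delta >= 0 branch threshold
    notes = ""
    ns_candidate = False
    if char.delta >= 0.0:
        if abs(a - thr_real) <= tol:
            verdict = "non-hyperbolic"
        elif a < thr_real:
            verdict = "sink"
        else:
            verdict = "source"
    else:
        # Delta < 0 forces beta < 1/2 here (else Delta = (ab+2)^2-4a could
        # still be negative only with the threshold defined), guard anyway.
        thr_c = 1.0 / (1.0 - 2.0 * b) if b < 0.5 else math.inf
        if abs(a - thr_c) <= tol:
            verdict = "non-hyperbolic"
            nr = nonresonance_check(b)
            ns_candidate = nr.passed
        elif a < thr_c:
            verdict = "sink"
        else:
            verdict = "source"

    eig_verdict = _eigen_verdict(lams, tol)
    consistent = verdict == eig_verdict
    if not consistent:
        notes = (
            "case-table verdict disagrees with eigenvalue moduli; "
            "the table is known to be unreliable on the Delta>=0, q<0 region"
        )
    return EquilibriumReport(
        label="A",
        location=A,
        char=char,
        eigenvalues=lams,
        classification=verdict,
        ns_candidate=ns_candidate,
        eigen_classification=eig_verdict,
        consistent=consistent,
        notes=notes,
    )


def ns_critical_alpha(beta: float) -> float:
    """The Neimark-Sacker critical parameter alpha_c(beta) = 1/(1-2*beta).

    Defined for 0 < beta < 1/2; the pair (alpha_c, beta) lies in H_A
    (Delta < 0 there is verified by :func:`membership_HA`).
    """
    beta = float(beta)
    if not 0.0 < beta < 0.5:
        raise ValueError(f"need 0 < beta < 1/2, got beta={beta}")
    return 1.0 / (1.0 - 2.0 * beta)


def transversality(beta: float) -> float:
    """Speed d|lambda|/d(alpha*) at the critical point: (1 - 2*beta)/2.

    Strictly positive on 0 < beta < 1/2 — the eigenvalue pair crosses the
    unit circle with nonzero speed, as the bifurcation requires.
    """
    beta = float(beta)
    if not 0.0 < beta < 0.5:
        raise ValueError(f"need 0 < beta < 1/2, got beta={beta}")
    return (1.0 - 2.0 * beta) / 2.0


def critical_eigenvalue(beta: float) -> complex:
    """The +Im member of the critical conjugate pair on H_A at this beta."""
    alpha = ns_critical_alpha(beta)
    c = char_coeffs(ModelParams(alpha=alpha, beta=beta))
    if c.delta >= 0.0:
        raise ValueError(
            f"Delta = {c.delta} >= 0 at the critical alpha; no complex pair"
        )
    return complex(c.p / 2.0, math.sqrt(-c.delta) / 2.0)


def resonance_distances(
    lam: complex,
) -> tuple[float, float, float, float]:
    """Distances |lambda^k - 1| for k = 1..4 (strong-resonance detector)."""
    return tuple(abs(lam**k - 1.0) for k in (1, 2, 3, 4))  # type: ignore[return-value]


def nonresonance_check(
    beta: float, tol: float = NONRESONANCE_TOL
) -> NonresonanceResult:
    """Check lambda^k != 1 for k = 1..4 at the critical parameter.

    Strong resonances (lambda a 1st–4th root of unity) break the generic
    Neimark-Sacker picture; the check passes iff every distance exceeds
    ``tol``.
    """
    lam = critical_eigenvalue(beta)
    d = resonance_distances(lam)
    return NonresonanceResult(passed=min(d) > tol, distances=d, lam=lam)


def membership_HA(
    params: ModelParams, tol: float = EQUALITY_TOL
) -> HAMembership:
    """Test (alpha, beta) against H_A = {Delta < 0, alpha = 1/(1-2*beta),
    beta < 1/2}.

    ``distance`` = alpha - 1/(1-2*beta) when beta < 1/2, else None.
    """
    a, b = params.alpha, params.beta
    if b >= 0.5:
        return HAMembership(in_HA=False, alpha_critical=None, distance=None)
    ac = 1.0 / (1.0 - 2.0 * b)
    dist = a - ac
    delta = char_coeffs(params).delta
    return HAMembership(
        in_HA=(abs(dist) <= tol and delta < 0.0),
        alpha_critical=ac,
        distance=dist,
    )
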