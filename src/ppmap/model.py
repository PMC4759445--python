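"""Core definitions of the discrete-time predator-prey map.

The model is the planar map

    x' = alpha * x * (1 - x) - x * y
    y' = (1 / beta) * x * y

on the closed first quadrant, where ``x`` is prey density, ``y`` predator
density, and ``alpha, beta > 0`` are dimensionless parameters (prey growth
rate and predation efficiency).  This module holds the map itself, its
Jacobian, the fixed points, and the characteristic-polynomial quantities
(p, q, Delta) that every other module consumes.

Sign convention: the characteristic polynomial at the interior equilibrium
is taken as ``lambda^2 - p*lambda + q = 0`` with p the trace and q the
determinant of the Jacobian, so that p = 2 - alpha*beta and
q = alpha - 2*alpha*beta.  This is the convention under which p and q agree
with the actual eigen-decomposition (a unit test enforces it).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "State",
    "Orbit",
    "CharCoeffs",
    "DivergenceError",
    "step",
    "jacobian",
    "equilibria",
    "char_coeffs",
    "eigenvalues_at",
]


class DivergenceError(RuntimeError):
    """An iterate left the finite / escape region.

    Carries the last finite pre-image and, when raised during iteration,
    the iteration index at which the orbit escaped.
    """

    def __init__(self, message: str, pre_image: "State | None" = None,
                 index: int | None = None):
        super().__init__(message)
        self.pre_image = pre_image
        self.index = index


@dataclass(frozen=True)
class ModelParams:
    """The parameter pair (alpha, beta); both must be strictly positive."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        alpha = float(self.alpha)
        beta = float(self.beta)
        if not (math.isfinite(alpha) and math.isfinite(beta)):
            raise ValueError("parameters must be finite")
        if alpha <= 0 or beta <= 0:
            raise ValueError(
                f"parameters must be positive: alpha={alpha}, beta={beta}"
            )
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "beta", beta)


@dataclass(frozen=True)
class State:
    """A point (x, y) in phase space; components are always finite.

    Divergence is reported through :class:`DivergenceError`, never stored.
    """

    x: float
    y: float

    def __post_init__(self) -> None:
        x, y = float(self.x), float(self.y)
        if not (math.isfinite(x) and math.isfinite(y)):
            raise ValueError(f"state components must be finite: ({x}, {y})")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class Orbit:
    """An ordered finite sequence of states produced by iterating the map.

    Invariant: each state is the exact floating-point image of its
    predecessor under :func:`step` at ``params`` (``validate`` rechecks it).
    ``transient_discarded`` records how many leading iterates were dropped
    before the stored window begins.
    """

    states: tuple[State, ...]
    params: ModelParams
    transient_discarded: int = 0

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[State]:
        return iter(self.states)

    def __getitem__(self, i):
        return self.states[i]

    def validate(self, indices: Sequence[int] | None = None) -> bool:
        """Recheck the one-step relation on ``indices`` (default: all steps).

        Exact equality is required: re-applying the map to a stored state
        is bitwise deterministic.
        """
        idx = range(len(self.states) - 1) if indices is None else indices
        for i in idx:
            image = step(self.states[i], self.params)
            nxt = self.states[i + 1]
            if image.x != nxt.x or image.y != nxt.y:
                return False
        return True


@dataclass(frozen=True)
class CharCoeffs:
    """Characteristic coefficients at the interior equilibrium.

    p = trace, q = determinant of J(A); delta = p^2 - 4q, which equals
    (alpha*beta + 2)^2 - 4*alpha identically.
    """

    p: float
    q: float
    delta: float

    def __post_init__(self) -> None:
        expected = self.p * self.p - 4.0 * self.q
        if not math.isclose(self.delta, expected, rel_tol=1e-12, abs_tol=1e-12):
            raise ValueError("delta must equal p^2 - 4q")


def step(s: State, params: ModelParams) -> State:
    """One application of the map.  Pure function.

    Raises :class:`DivergenceError` if the image is non-finite (overflow),
    carrying the offending pre-image.
    """
    a, b = params.alpha, params.beta
    x1 = a * s.x * (1.0 - s.x) - s.x * s.y
    y1 = (s.x * s.y) / b
    if not (math.isfinite(x1) and math.isfinite(y1)):
        raise DivergenceError(
            f"map image non-finite from ({s.x}, {s.y})", pre_image=s
        )
    return State(x1, y1)


def jacobian(s: State, params: ModelParams) -> np.ndarray:
    """Jacobian matrix of the map at ``s``:

    [[alpha - 2*alpha*x - y,  -x],
     [y/beta,                  x/beta]]
    """
    a, b = params.alpha, params.beta
    return np.array(
        [
            [a - 2.0 * a * s.x - s.y, -s.x],
            [s.y / b, s.x / b],
        ],
        dtype=float,
    )


def interior_equilibrium(params: ModelParams) -> State:
    """The coexistence fixed point A = (beta, alpha*(1-beta) - 1).

    Returned regardless of admissibility; use :func:`equilibria` for the
    existence-filtered list.
    """
    a, b = params.alpha, params.beta
    return State(b, a * (1.0 - b) - 1.0)


def interior_exists(params: ModelParams) -> bool:
    """True iff A lies in the open first quadrant: beta < 1 and
    alpha > 1/(1-beta)."""
    a, b = params.alpha, params.beta
    return b < 1.0 and a > 1.0 / (1.0 - b)


def equilibria(
    params: ModelParams, include_nonadmissible: bool = False
) -> list[tuple[str, State]]:
    """Fixed points of the map as (label, state) pairs.

    Always contains ("O", (0,0)).  Contains ("A", (beta, alpha*(1-beta)-1))
    exactly when beta < 1 and alpha > 1/(1-beta); with
    ``include_nonadmissible`` the interior fixed point is returned even when
    its predator component is non-positive (it is still a fixed point of the
    algebraic map, just biologically meaningless).
    """
    out: list[tuple[str, State]] = [("O", State(0.0, 0.0))]
    if interior_exists(params) or include_nonadmissible:
        out.append(("A", interior_equilibrium(params)))
    return out


def char_coeffs(params: ModelParams) -> CharCoeffs:
    """p, q, Delta of the characteristic polynomial at A.

    p = 2 - alpha*beta, q = alpha - 2*alpha*beta, Delta = p^2 - 4q
    = (alpha*beta + 2)^2 - 4*alpha.
    """
    a, b = params.alpha, params.beta
    p = 2.0 - a * b
    q = a - 2.0 * a * b
    return CharCoeffs(p=p, q=q, delta=p * p - 4.0 * q)


def eigenvalues_at(s: State, params: ModelParams) -> tuple[complex, complex]:
    """Eigenvalues of the Jacobian at ``s``, ordered by (Re, Im) descending.

    A conjugate pair is therefore always returned with the +Im member first.
    """
    vals = np.linalg.eigvals(jacobian(s, params))
    lams = sorted(
        (complex(v) for v in vals), key=lambda z: (z.real, z.imag), reverse=True
    )
    return lams[0], lams[1]
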