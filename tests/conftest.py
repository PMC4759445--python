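"""Shared fixtures and finite-difference helpers.

The finite-difference oracles here differentiate the *map itself* (or the
translated/transformed maps), independently of the closed-form expressions
they are used to verify.
"""

from __future__ import annotations

import numpy as np
import pytest

from ppmap.model import ModelParams, State, step
from ppmap.stability import ns_critical_alpha

BETA_REF = 0.23
ALPHA_CRIT_REF = 1.0 / (1.0 - 2.0 * BETA_REF)  # = 1.85185185...


@pytest.fixture
def params_stable() -> ModelParams:
    """Sink regime of the reference simulation (alpha = 1.48)."""
    return ModelParams(alpha=1.48, beta=BETA_REF)


@pytest.fixture
def params_critical() -> ModelParams:
    """On the Neimark-Sacker locus H_A at beta = 0.23."""
    return ModelParams(alpha=ALPHA_CRIT_REF, beta=BETA_REF)


@pytest.fixture
def params_circle() -> ModelParams:
    """Just past critical: an attracting invariant circle exists."""
    return ModelParams(alpha=1.87, beta=BETA_REF)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)


def random_HA_params(rng: np.random.Generator, n: int,
                     lo: float = 0.05, hi: float = 0.45) -> list[ModelParams]:
    """n random points on the critical locus, beta uniform in (lo, hi).

    Membership in H_A also needs Delta < 0, which on alpha = 1/(1-2*beta)
    holds only for beta < 4/9; draws violating it are rejected and redrawn.
    """
    out: list[ModelParams] = []
    while len(out) < n:
        b = float(rng.uniform(lo, hi))
        p = ModelParams(alpha=ns_critical_alpha(b), beta=b)
        if (p.alpha * p.beta + 2.0) ** 2 - 4.0 * p.alpha < 0.0:
            out.append(p)
    return out


def fd_jacobian(s: State, params: ModelParams, h: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian of step() at s."""

    def f(x: float, y: float) -> np.ndarray:
        return step(State(x, y), params).as_array()

    col_x = (f(s.x + h, s.y) - f(s.x - h, s.y)) / (2 * h)
    col_y = (f(s.x, s.y + h) - f(s.x, s.y - h)) / (2 * h)
    return np.column_stack([col_x, col_y])


def fd_quadratic_coeffs(f, h: float = 1e-4) -> dict[str, float]:
    """Linear and quadratic Taylor coefficients of a planar map component
    f(u, v) -> float around the origin, by central differences.

    Returns {u, v, uu, uv, vv}: f ~ u*du + v*dv + uu*u^2 + uv*u*v + vv*v^2.
    """
    f00 = f(0.0, 0.0)
    du = (f(h, 0.0) - f(-h, 0.0)) / (2 * h)
    dv = (f(0.0, h) - f(0.0, -h)) / (2 * h)
    duu = (f(h, 0.0) - 2 * f00 + f(-h, 0.0)) / (h * h) / 2.0
    dvv = (f(0.0, h) - 2 * f00 + f(0.0, -h)) / (h * h) / 2.0
    duv = (f(h, h) - f(h, -h) - f(-h, h) + f(-h, -h)) / (4 * h * h)
    return {"u": du, "v": dv, "uu": duu, "uv": duv, "vv": dvv}
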