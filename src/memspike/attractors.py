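"""Per-manifold equilibrium stability and attractor classification.

Each invariant manifold ``M(Q0)`` of the input-less circuit carries a
unique equilibrium at ``(qM, iL) = (Q0, 0)``.  Its planar Jacobian is

    J(Q0) = [[0, 1], [-1/(L*C), (s1/L) * (q_bar**2 - Q0**2)]],

where ``q_bar = sqrt((s0 - R)/s1)`` is the charge threshold.  The
determinant ``1/(L*C)`` is always positive, so the equilibrium is a focus
or center, never a saddle; the sign of the trace -- i.e. of
``q_bar**2 - Q0**2`` -- decides stability.  For ``|Q0| > q_bar`` the
equilibrium is asymptotically stable and is the manifold's attractor; for
``|Q0| < q_bar`` it is unstable and the manifold's attractor is a stable
limit cycle surrounding it.  At ``|Q0| = q_bar`` the eigenvalues are purely
imaginary: a Hopf-like transition reached by moving the *initial
conditions*, not any circuit parameter (a bifurcation without parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .circuit import CircuitParams

__all__ = [
    "Stability",
    "AttractorType",
    "EquilibriumReport",
    "q_bar",
    "jacobian_at",
    "eigenvalues_at",
    "default_tol_band",
    "classify",
]


class Stability(str, Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    CRITICAL = "critical"


class AttractorType(str, Enum):
    EQUILIBRIUM = "equilibrium"
    LIMIT_CYCLE = "limit_cycle"
    BOUNDARY = "boundary"


@dataclass(frozen=True)
class EquilibriumReport:
    """Stability report for the equilibrium of one invariant manifold."""

    Q0: float
    location: tuple[float, float]
    eigenvalues: tuple[complex, complex]
    stability: Stability
    attractor_type: AttractorType


def q_bar(params: CircuitParams) -> float:
    """Charge threshold ``sqrt((s0 - R)/s1)`` separating stable-equilibrium
    manifolds (``|Q0| > q_bar``) from limit-cycle manifolds."""
    return math.sqrt((params.s0 - params.R) / params.s1)


def jacobian_at(params: CircuitParams, Q0: float) -> np.ndarray:
    """Jacobian of the planar manifold dynamics at the equilibrium
    ``(Q0, 0)``."""
    qb2 = (params.s0 - params.R) / params.s1
    return np.array(
        [
            [0.0, 1.0],
            [-1.0 / (params.L * params.C), (params.s1 / params.L) * (qb2 - Q0**2)],
        ]
    )


def eigenvalues_at(params: CircuitParams, Q0: float) -> tuple[complex, complex]:
    """Closed-form eigenvalues of :func:`jacobian_at`.

    From the characteristic quadratic ``lam**2 - tr*lam + det = 0`` with
    ``tr = (s1/L)*(q_bar**2 - Q0**2)`` and ``det = 1/(L*C)``; exact up to a
    square root, preserving the conjugate-pair structure.
    """
    tr = (params.s1 / params.L) * ((params.s0 - params.R) / params.s1 - Q0**2)
    det = 1.0 / (params.L * params.C)
    disc = tr * tr - 4.0 * det
    if disc >= 0.0:
        root = math.sqrt(disc)
        return (complex((tr - root) / 2.0), complex((tr + root) / 2.0))
    root = math.sqrt(-disc)
    return (complex(tr / 2.0, -root / 2.0), complex(tr / 2.0, root / 2.0))


def default_tol_band(params: CircuitParams) -> float:
    """Dead-zone half-width around ``|Q0| = q_bar`` inside which the
    classification is reported as critical/boundary.

    Exact coincidence with the threshold is numerically meaningless; a
    small relative band makes the "critical" label reproducible.
    """
    return 1e-9 * max(1.0, q_bar(params))


def classify(
    params: CircuitParams, Q0: float, tol_band: float | None = None
) -> EquilibriumReport:
    """Classify the equilibrium of ``M(Q0)`` and the manifold's attractor.

    Within ``tol_band`` of the threshold the stability is ``critical`` and
    the attractor type ``boundary``; otherwise ``|Q0| > q_bar`` gives a
    stable equilibrium and ``|Q0| < q_bar`` an unstable equilibrium
    surrounded by the manifold's stable limit cycle.
    """
    if tol_band is None:
        tol_band = default_tol_band(params)
    qb = q_bar(params)
    eigs = eigenvalues_at(params, Q0)
    if abs(abs(Q0) - qb) <= tol_band:
        stability, attractor = Stability.CRITICAL, AttractorType.BOUNDARY
    elif abs(Q0) > qb:
        stability, attractor = Stability.STABLE, AttractorType.EQUILIBRIUM
    else:
        stability, attractor = Stability.UNSTABLE, AttractorType.LIMIT_CYCLE
    return EquilibriumReport(
        Q0=Q0,
        location=(Q0, 0.0),
        eigenvalues=eigs,
        stability=stability,
        attractor_type=attractor,
    )
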