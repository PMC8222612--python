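"""Core circuit model: parameters, memristor characteristic, dynamical forms.

The circuit is a capacitor ``C`` in parallel with an independent current
source ``Is(t)``, closed through a series branch containing a resistor
``R``, an inductor ``L`` and an ideal charge-controlled memristor.  The
memristor has an odd linear-plus-cubic flux--charge characteristic

    phi(q) = -s0 * q + (s1 / 3) * q**3,        s0 > R,  s1 > 0.

Three equivalent state-space forms of the dynamics are provided:

* :func:`rhs_full`     -- natural states ``(vC, qM, iL)``;
* :func:`rhs_qcoords`  -- states ``(Q, qM, iL)`` with ``Q = qM + C*vC``,
  where ``Q`` integrates the source current directly (``dQ/dt = Is``);
* :func:`rhs_manifold` -- the planar restriction ``(qM, iL)`` to the
  invariant manifold ``M(Q0)``.

With ``Is = 0`` the combination ``Q = qM + C*vC`` is conserved, so the
state space is foliated into planar invariant manifolds ``M(Q0)``, one per
value of the manifold index ``Q0``.  All quantities are in normalized
(dimensionless) units, including time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CircuitParams",
    "REFERENCE_PARAMS",
    "StateVC",
    "StateQ",
    "to_qcoords",
    "to_vccoords",
    "phi_hat",
    "manifold_index",
    "rhs_full",
    "rhs_qcoords",
    "rhs_manifold",
]


@dataclass(frozen=True)
class CircuitParams:
    """The five normalized circuit constants.

    Attributes
    ----------
    R : float
        Series resistance.
    L : float
        Inductance.
    C : float
        Capacitance.
    s0 : float
        Linear coefficient of the memristor characteristic.
    s1 : float
        Cubic coefficient of the memristor characteristic.

    ``s0 > R`` and ``s1 > 0`` are required: every stability and design
    formula downstream needs a real positive charge threshold
    ``sqrt((s0 - R) / s1)``.
    """

    R: float
    L: float
    C: float
    s0: float
    s1: float

    def __post_init__(self) -> None:
        for name in ("R", "L", "C", "s0", "s1"):
            value = getattr(self, name)
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise TypeError(f"{name} must be a real number, got {value!r}")
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")
        if self.s0 <= self.R:
            raise ValueError(
                f"memristor linear coefficient s0={self.s0} must exceed R={self.R}; "
                "otherwise no oscillatory manifold exists"
            )

    @property
    def omega0(self) -> float:
        """Natural angular frequency ``1/sqrt(L*C)`` of the linear L-C pair."""
        return 1.0 / math.sqrt(self.L * self.C)


#: Reference parameter set used throughout the documentation and tests.
REFERENCE_PARAMS = CircuitParams(R=0.4, L=1.5, C=0.1, s0=0.7, s1=0.3)


def _check_finite(**fields: float) -> None:
    for name, value in fields.items():
        if not math.isfinite(value):
            raise ValueError(f"state component {name} must be finite, got {value!r}")


@dataclass(frozen=True)
class StateVC:
    """Circuit state in natural coordinates (capacitor voltage, memristor
    charge, inductor current)."""

    vC: float
    qM: float
    iL: float

    def __post_init__(self) -> None:
        _check_finite(vC=self.vC, qM=self.qM, iL=self.iL)

    def __iter__(self):
        yield from (self.vC, self.qM, self.iL)


@dataclass(frozen=True)
class StateQ:
    """Circuit state in manifold coordinates ``(Q, qM, iL)`` with
    ``Q = qM + C*vC``."""

    Q: float
    qM: float
    iL: float

    def __post_init__(self) -> None:
        _check_finite(Q=self.Q, qM=self.qM, iL=self.iL)

    def __iter__(self):
        yield from (self.Q, self.qM, self.iL)


def to_qcoords(state: StateVC, params: CircuitParams) -> StateQ:
    """Convert a natural-coordinate state to manifold coordinates."""
    return StateQ(Q=state.qM + params.C * state.vC, qM=state.qM, iL=state.iL)


def to_vccoords(state: StateQ, params: CircuitParams) -> StateVC:
    """Convert a manifold-coordinate state back to natural coordinates."""
    return StateVC(vC=(state.Q - state.qM) / params.C, qM=state.qM, iL=state.iL)


def phi_hat(qM, params: CircuitParams):
    """Memristor flux as a function of charge: ``-s0*q + (s1/3)*q**3``.

    Odd in ``qM``; accepts scalars or numpy arrays.
    """
    return -params.s0 * qM + (params.s1 / 3.0) * qM**3


def manifold_index(state, params: CircuitParams) -> float:
    """The conserved combination ``Q0 = qM + C*vC`` labelling the invariant
    manifold that contains ``state`` (natural coordinates)."""
    vC, qM, _iL = state
    return qM + params.C * vC


def rhs_full(t, state, Is: float, params: CircuitParams) -> np.ndarray:
    """Time derivative of ``(vC, qM, iL)`` for the full third-order model.

    ``d(vC)/dt = (Is - iL)/C``, ``d(qM)/dt = iL`` and
    ``d(iL)/dt = (vC + (s0 - R)*iL - s1*qM**2*iL)/L``.
    """
    vC, qM, iL = state
    return np.array(
        [
            (Is - iL) / params.C,
            iL,
            (vC + (params.s0 - params.R) * iL - params.s1 * qM**2 * iL) / params.L,
        ]
    )


def rhs_qcoords(t, state, Is: float, params: CircuitParams) -> np.ndarray:
    """Time derivative of ``(Q, qM, iL)``.

    ``Q`` integrates the input directly: ``dQ/dt = Is``.  The remaining two
    equations are the planar manifold dynamics with the (generally moving)
    index ``Q``.
    """
    Q, qM, iL = state
    return np.array(
        [
            Is,
            iL,
            (Q - qM) / (params.L * params.C)
            + ((params.s0 - params.R) - params.s1 * qM**2) * iL / params.L,
        ]
    )


def rhs_manifold(t, planar_state, Q0: float, params: CircuitParams) -> np.ndarray:
    """Time derivative of ``(qM, iL)`` restricted to the invariant manifold
    ``M(Q0)`` (the input-less dynamics with the index frozen at ``Q0``)."""
    qM, iL = planar_state
    return np.array(
        [
            iL,
            (Q0 - qM) / (params.L * params.C)
            + ((params.s0 - params.R) - params.s1 * qM**2) * iL / params.L,
        ]
    )
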