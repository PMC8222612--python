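"""Describing-function (harmonic balance) prediction of the limit cycles.

The planar manifold dynamics admits a Lur'e input--output form

    qM = -L(D) phi(qM) + L0(D) Q0,

with the linear blocks

    L(D)  = (D/L)      / (D**2 + (R/L) D + 1/(L*C)),
    L0(D) = (1/(L*C))  / (D**2 + (R/L) D + 1/(L*C)).

``L(s)`` is the admittance the memristor sees looking into the rest of the
circuit (R, L and C in series).  Under a bias-plus-sinusoid ansatz
``qM(t) = A + B cos(omega t)`` the cubic nonlinearity is quasi-linearized
by the describing-function gains ``N0`` (bias) and ``N1`` (first
harmonic); balancing the bias and first-harmonic loop equations gives the
Predicted Limit Cycle (PLC) in closed form:

    A = Q0,   omega = 1/sqrt(L*C),   B**2 = 4*(q_bar**2 - Q0**2),

which exists exactly on the manifolds with ``|Q0| < q_bar``.  In the
``(qM, iL)`` plane the PLC is the ellipse
``(qM - Q0)**2 + L*C*iL**2 = B**2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .attractors import default_tol_band, q_bar
from .circuit import CircuitParams

__all__ = [
    "DFGains",
    "PLC",
    "eval_L",
    "eval_L0",
    "df_gains",
    "hb_residuals",
    "solve_plc",
    "plc_waveform",
    "plc_extrema",
]


def _denominator(params: CircuitParams, s: complex) -> complex:
    return s * s + (params.R / params.L) * s + 1.0 / (params.L * params.C)


def eval_L(params: CircuitParams, s: complex) -> complex:
    """Feedback-block transfer function ``L(s)`` (memristor-port admittance)."""
    den = _denominator(params, s)
    if den == 0:
        raise ZeroDivisionError(f"s={s} is a pole of the linear block")
    return (s / params.L) / den


def eval_L0(params: CircuitParams, s: complex) -> complex:
    """Feed-forward transfer function ``L0(s)`` from the manifold index to
    the charge; ``L0(0) = 1``."""
    den = _denominator(params, s)
    if den == 0:
        raise ZeroDivisionError(f"s={s} is a pole of the linear block")
    return (1.0 / (params.L * params.C)) / den


@dataclass(frozen=True)
class DFGains:
    """Describing-function gains of the cubic characteristic under the
    input ``A + B cos(omega t)``: ``N0`` multiplies the bias ``A``, ``N1``
    the first harmonic ``B cos``."""

    N0: float
    N1: float


def df_gains(A: float, B: float, params: CircuitParams) -> DFGains:
    """Bias and first-harmonic describing-function gains.

    ``N0 = -s0 + (s1/3)*(A**2 + (3/2)*B**2)`` and
    ``N1 = -s0 + s1*(A**2 + (1/4)*B**2)``.  These are exactly the Fourier
    mean and first-cosine coefficient of ``phi(A + B cos t)`` divided by
    ``A`` and ``B`` respectively.
    """
    N0 = -params.s0 + (params.s1 / 3.0) * (A**2 + 1.5 * B**2)
    N1 = -params.s0 + params.s1 * (A**2 + 0.25 * B**2)
    return DFGains(N0=N0, N1=N1)


def hb_residuals(
    A: float, B: float, omega: float, Q0: float, params: CircuitParams
) -> tuple[float, complex]:
    """Harmonic-balance residuals of the bias and first-harmonic loop
    equations; both vanish at a PLC.

    The bias residual is ``A + L(0)*N0*A - L0(0)*Q0`` (which reduces to
    ``A - Q0`` for this circuit since ``L(0) = 0`` and ``L0(0) = 1``); the
    harmonic residual is ``1 + L(j*omega)*N1``.
    """
    gains = df_gains(A, B, params)
    bias = A + eval_L(params, 0.0).real * gains.N0 * A - eval_L0(params, 0.0).real * Q0
    harmonic = 1.0 + eval_L(params, 1j * omega) * gains.N1
    return float(bias), complex(harmonic)


@dataclass(frozen=True)
class PLC:
    """Closed-form Predicted Limit Cycle on the manifold ``M(Q0)``:
    ``qM(t) = A_hat + B_hat*cos(omega_hat*t)``."""

    Q0: float
    A_hat: float
    B_hat: float
    omega_hat: float
    period: float


def solve_plc(
    params: CircuitParams, Q0: float, tol_band: float | None = None
) -> PLC | None:
    """Solve the harmonic-balance equations for the PLC on ``M(Q0)``.

    Returns ``None`` when ``|Q0| >= q_bar`` (within ``tol_band``): the
    predicted amplitude collapses to zero at the threshold and no limit
    cycle exists beyond it, so absence of a PLC is an ordinary value for
    callers sweeping Q0 grids, not an error.
    """
    if tol_band is None:
        tol_band = default_tol_band(params)
    qb = q_bar(params)
    if abs(Q0) >= qb - tol_band:
        return None
    B_hat = 2.0 * math.sqrt(qb**2 - Q0**2)
    omega_hat = params.omega0
    return PLC(Q0=Q0, A_hat=Q0, B_hat=B_hat, omega_hat=omega_hat, period=2.0 * math.pi / omega_hat)


def plc_waveform(plc: PLC, t):
    """Sample the PLC: ``qM = A_hat + B_hat*cos(w t)``,
    ``iL = -B_hat*w*sin(w t)``.  Accepts scalars or arrays."""
    phase = plc.omega_hat * np.asarray(t, dtype=float)
    qM = plc.A_hat + plc.B_hat * np.cos(phase)
    iL = -plc.B_hat * plc.omega_hat * np.sin(phase)
    if np.ndim(t) == 0:
        return float(qM), float(iL)
    return qM, iL


def plc_extrema(plc: PLC) -> tuple[float, float]:
    """Minimum and maximum of the PLC charge over one period:
    ``Q0 -+ 2*sqrt(q_bar**2 - Q0**2)``."""
    return (plc.A_hat - plc.B_hat, plc.A_hat + plc.B_hat)
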