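"""Pulse-timing design: making the memristor charge spike like a neuron.

A current pulse of area ``Lambda`` moves the state from manifold
``M(Q0)`` to ``M(Q0 + Lambda)`` (the index integrates the source
current).  The design exploits this to concatenate a resting phase on a
stable-equilibrium manifold, an oscillation window on a limit-cycle
manifold, and a reset back to rest:

* set pulse of area ``+Lambda`` and small width ``Delta`` at the stimulus
  time ``t_i`` moves the resting state onto the oscillatory manifold;
* the charge traces ``n`` periods of the limit cycle (one period = one
  spike of the "membrane potential" ``qM``);
* a reset pulse of area ``-Lambda`` at ``t_i + Delta + n*T`` returns the
  state to the resting manifold.

For a clean spike the post-pulse state ``(qM, iL) ~ (Q0_init, 0)`` must
land exactly on the limit cycle's minimum, i.e.
``Q0_init = Q0 - 2*sqrt(q_bar**2 - Q0**2)`` with ``Q0 = Q0_init + Lambda``.
Among the manifold pairs satisfying this, the design takes the one with
the smallest ``Q0_init`` (deepest resting manifold): it maximizes the
distance from the critical manifold and hence robustness against spurious
small-area pulses.  Minimizing the right-hand side in closed form gives

    Q0_target = -q_bar/sqrt(5),  Q0_init = -sqrt(5)*q_bar,
    Lambda = (4/sqrt(5))*q_bar,  T = 2*pi*sqrt(L*C),
    Delta = 2*sigma*pi*sqrt(L*C)    (sigma in [0.01, 0.05]).

Note: the pulse area is written both as ``Lambda`` and ``A`` in the
harmonic-balance literature; this module uses the single field ``area``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .attractors import q_bar
from .circuit import CircuitParams

__all__ = [
    "Pulse",
    "StimulusProgram",
    "EMPTY_STIMULUS",
    "SpikeDesign",
    "PredictedResponse",
    "SIGMA_RANGE",
    "DEFAULT_SIGMA",
    "design_spike",
    "matching_residual",
    "build_stimulus",
    "predicted_response",
]

#: Recommended range for the pulse-width fraction sigma = Delta / T.
SIGMA_RANGE = (0.01, 0.05)
DEFAULT_SIGMA = 0.02


@dataclass(frozen=True)
class Pulse:
    """A finite-width current pulse delivering a signed charge ``area``
    over ``[t_start, t_start + width)``; rectangular shape has constant
    height ``area/width``."""

    t_start: float
    area: float
    width: float
    shape: str = "rectangular"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.t_start) and math.isfinite(self.area)):
            raise ValueError("pulse start and area must be finite")
        if not (math.isfinite(self.width) and self.width > 0):
            raise ValueError(f"pulse width must be positive, got {self.width!r}")
        if self.shape != "rectangular":
            raise ValueError(f"unsupported pulse shape {self.shape!r}")

    @property
    def t_end(self) -> float:
        return self.t_start + self.width

    @property
    def height(self) -> float:
        return self.area / self.width

    def current(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where((t >= self.t_start) & (t < self.t_end), self.height, 0.0)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StimulusProgram:
    """An ordered, non-overlapping sequence of pulses defining ``Is(t)``
    (zero outside every pulse support)."""

    pulses: tuple[Pulse, ...] = ()

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.pulses, key=lambda p: p.t_start))
        object.__setattr__(self, "pulses", ordered)
        for prev, nxt in zip(ordered, ordered[1:]):
            if nxt.t_start < prev.t_end:
                raise ValueError(
                    f"pulses overlap: one ends at t={prev.t_end} but the next "
                    f"starts at t={nxt.t_start}"
                )

    def current(self, t):
        """Source current ``Is(t)``; scalar or array input."""
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for p in self.pulses:
            out = out + p.current(t)
        return float(out) if out.ndim == 0 else out

    def edges(self) -> list[float]:
        """Sorted pulse start/end times (integration breakpoints)."""
        times: set[float] = set()
        for p in self.pulses:
            times.add(p.t_start)
            times.add(p.t_end)
        return sorted(times)

    def total_area(self) -> float:
        return sum(p.area for p in self.pulses)


EMPTY_STIMULUS = StimulusProgram(())


@dataclass(frozen=True)
class SpikeDesign:
    """The designed spike quadruple for a given parameter set.

    ``T`` is the oscillation period (one spike), ``Q0_init`` the resting
    manifold index, ``Lambda`` the set-pulse area, ``Delta`` the pulse
    width (= ``sigma*T``), and ``Q0_target = Q0_init + Lambda`` the
    oscillatory manifold index.
    """

    params: CircuitParams
    sigma: float
    T: float
    Q0_init: float
    Lambda: float
    Delta: float
    Q0_target: float


def design_spike(params: CircuitParams, sigma: float = DEFAULT_SIGMA) -> SpikeDesign:
    """Compute the spike design in closed form from the circuit parameters.

    ``sigma`` is the pulse width as a fraction of the period; values
    outside ``[0.01, 0.05]`` are accepted with a warning (the width rule is
    a heuristic: small enough that the charge barely moves during the
    pulse, large enough to be realizable).
    """
    if not (SIGMA_RANGE[0] <= sigma <= SIGMA_RANGE[1]):
        warnings.warn(
            f"sigma={sigma} lies outside the recommended range {SIGMA_RANGE}; "
            "the pulse-width heuristic may be inaccurate",
            stacklevel=2,
        )
    qb = q_bar(params)
    T = 2.0 * math.pi * math.sqrt(params.L * params.C)
    Q0_target = -qb / math.sqrt(5.0)
    Q0_init = -math.sqrt(5.0) * qb
    Lambda = (4.0 / math.sqrt(5.0)) * qb
    Delta = 2.0 * sigma * math.pi * math.sqrt(params.L * params.C)
    return SpikeDesign(
        params=params,
        sigma=sigma,
        T=T,
        Q0_init=Q0_init,
        Lambda=Lambda,
        Delta=Delta,
        Q0_target=Q0_target,
    )


def matching_residual(Q0_init: float, Q0: float, params: CircuitParams) -> float:
    """Residual of the spike matching condition
    ``Q0_init = Q0 - 2*sqrt(q_bar**2 - Q0**2)``.

    Zero iff a state resting at ``(Q0_init, 0)`` lands exactly on the
    minimum of the predicted limit cycle of ``M(Q0)`` after an
    (infinitesimally short) pulse of area ``Q0 - Q0_init``.
    """
    qb = q_bar(params)
    if abs(Q0) > qb:
        raise ValueError(
            f"|Q0|={abs(Q0)} exceeds the threshold {qb}: no limit cycle on that manifold"
        )
    return Q0_init - (Q0 - 2.0 * math.sqrt(qb**2 - Q0**2))


def build_stimulus(
    design: SpikeDesign,
    t_i: float = 0.0,
    n_spikes: int = 1,
    spike_times: list[float] | None = None,
) -> StimulusProgram:
    """Build the set/reset pulse program for one or more spike events.

    Each event at time ``t`` contributes a set pulse ``(t, +Lambda,
    Delta)`` and a reset pulse ``(t + Delta + n_spikes*T, -Lambda,
    Delta)``; with ``n_spikes > 1`` the oscillation window covers
    ``n_spikes`` periods (a burst).  Events must be separated by more than
    ``Delta + n_spikes*T + Delta``.
    """
    if n_spikes < 1:
        raise ValueError("n_spikes must be a positive integer")
    times = sorted(spike_times) if spike_times is not None else [t_i]
    min_sep = design.Delta + n_spikes * design.T + design.Delta
    for a, b in zip(times, times[1:]):
        if b - a <= min_sep:
            raise ValueError(
                f"spike events at t={a} and t={b} are closer than the "
                f"required separation {min_sep}"
            )
    pulses = []
    for t in times:
        pulses.append(Pulse(t_start=t, area=design.Lambda, width=design.Delta))
        pulses.append(
            Pulse(
                t_start=t + design.Delta + n_spikes * design.T,
                area=-design.Lambda,
                width=design.Delta,
            )
        )
    return StimulusProgram(tuple(pulses))


@dataclass(frozen=True)
class PredictedResponse:
    """Idealized piecewise charge waveform for one spike/burst event.

    Constant at ``Q0_init`` outside the oscillation window
    ``(t_on, t_off) = (t_i + Delta, t_i + Delta + n_spikes*T)``; inside it
    follows the predicted limit cycle of the target manifold starting at
    its minimum (phase ``pi``):

        qM0(t) = Q0_target + B*cos(omega*(t - t_on) + pi),

    with ``B = 2*sqrt(q_bar**2 - Q0_target**2)``.  ``iL0`` is the
    derivative, with one-sided values at the window edges (where it is
    zero under the phase-``pi`` convention, so the waveform has no kinks
    in ``qM0``).
    """

    design: SpikeDesign
    t_i: float
    n_spikes: int = 1
    B_target: float = field(init=False)

    def __post_init__(self) -> None:
        qb = q_bar(self.design.params)
        object.__setattr__(
            self, "B_target", 2.0 * math.sqrt(qb**2 - self.design.Q0_target**2)
        )

    @property
    def t_on(self) -> float:
        return self.t_i + self.design.Delta

    @property
    def t_off(self) -> float:
        return self.t_on + self.n_spikes * self.design.T

    def qM0(self, t):
        t_arr = np.asarray(t, dtype=float)
        omega = self.design.params.omega0
        inside = (t_arr > self.t_on) & (t_arr < self.t_off)
        osc = self.design.Q0_target + self.B_target * np.cos(
            omega * (t_arr - self.t_on) + math.pi
        )
        out = np.where(inside, osc, self.design.Q0_init)
        return float(out) if out.ndim == 0 else out

    def iL0(self, t):
        t_arr = np.asarray(t, dtype=float)
        omega = self.design.params.omega0
        inside = (t_arr > self.t_on) & (t_arr < self.t_off)
        der = -self.B_target * omega * np.sin(omega * (t_arr - self.t_on) + math.pi)
        out = np.where(inside, der, 0.0)
        return float(out) if out.ndim == 0 else out


def predicted_response(
    design: SpikeDesign, t_i: float, n_spikes: int = 1
) -> PredictedResponse:
    """Predicted charge/current waveform for a single spike (or burst)
    event starting at ``t_i``."""
    if n_spikes < 1:
        raise ValueError("n_spikes must be a positive integer")
    return PredictedResponse(design=design, t_i=t_i, n_spikes=n_spikes)
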