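"""Numerical integration under pulse stimulation and limit-cycle extraction.

Any of the three model forms can be integrated under a
:class:`~memspike.pulse_design.StimulusProgram`.  Pulse edges are hard
integration breakpoints: the solver is stopped and restarted at every edge
with the source current constant on each segment, so the delivered pulse
area is exact (never smeared by the step controller across a
discontinuity).  Since Runge--Kutta methods preserve linear invariants,
the manifold index ``Q = qM + C*vC`` is conserved on source-free segments
to roundoff, which the default tolerances (rtol=1e-9, atol=1e-12) make a
meaningful test quantity.

Utilities classify the asymptotic outcome (equilibrium vs. oscillation),
estimate the true limit cycle's period and charge extrema from upward
zero-crossings of ``iL`` (which occur exactly at charge minima), and
compare the numeric cycle against the closed-form PLC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .circuit import CircuitParams, rhs_full, rhs_manifold, rhs_qcoords
from .describing_function import PLC, plc_extrema, solve_plc
from .attractors import q_bar
from .pulse_design import EMPTY_STIMULUS, StimulusProgram

__all__ = [
    "IntegrationSettings",
    "Trajectory",
    "Outcome",
    "CycleEstimate",
    "PLCComparison",
    "integrate",
    "classify_outcome",
    "extract_cycle",
    "compare_plc",
]

_FORMS = ("full", "qcoords", "manifold")


@dataclass(frozen=True)
class IntegrationSettings:
    """Solver configuration: tolerances, step bound and output grid step."""

    rtol: float = 1e-9
    atol: float = 1e-12
    max_step: float = math.inf
    dt: float = 0.01
    method: str = "DOP853"

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.dt <= 0:
            raise ValueError("output grid step dt must be positive")
        if self.max_step <= 0:
            raise ValueError("max_step must be positive")


DEFAULT_SETTINGS = IntegrationSettings()


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped samples of the state in manifold coordinates
    ``(Q, qM, iL)``, together with the stimulus and parameters used."""

    t: np.ndarray
    Q: np.ndarray
    qM: np.ndarray
    iL: np.ndarray
    params: CircuitParams
    stimulus: StimulusProgram

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def vC(self) -> np.ndarray:
        """Capacitor voltage recovered from ``(Q - qM)/C``."""
        return (self.Q - self.qM) / self.params.C

    @property
    def Is(self) -> np.ndarray:
        """Source current sampled on the trajectory grid."""
        return np.asarray(self.stimulus.current(self.t))


def _output_grid(t0: float, t1: float, dt: float, edges: list[float]) -> np.ndarray:
    n = int(math.ceil((t1 - t0) / dt))
    grid = t0 + dt * np.arange(n + 1)
    grid[-1] = min(grid[-1], t1)
    grid = np.union1d(grid, np.asarray(edges, dtype=float))
    return grid[(grid >= t0) & (grid <= t1)]


def integrate(
    form: str,
    initial,
    stimulus: StimulusProgram,
    t_span: tuple[float, float],
    params: CircuitParams,
    settings: IntegrationSettings | None = None,
) -> Trajectory:
    """Integrate the circuit under a stimulus program.

    Parameters
    ----------
    form : {"full", "qcoords", "manifold"}
        Which equivalent model to integrate.  ``"manifold"`` integrates
        the planar restriction and requires an empty stimulus (the index
        is frozen).
    initial : state
        ``StateVC`` or ``(vC, qM, iL)`` for ``"full"``; ``StateQ`` or
        ``(Q, qM, iL)`` for ``"qcoords"`` and ``"manifold"``.
    stimulus : StimulusProgram
        Pulse program; edges become hard integration breakpoints.
    t_span : (t0, t1)
        Integration interval.
    settings : IntegrationSettings, optional

    Returns
    -------
    Trajectory
        Sampled on a uniform grid of step ``settings.dt`` augmented with
        the pulse edges, always in ``(Q, qM, iL)`` coordinates.
    """
    if form not in _FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {_FORMS}")
    if settings is None:
        settings = DEFAULT_SETTINGS
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError(f"t_span must be increasing, got {t_span}")

    a, b, c = (float(v) for v in initial)

    if form == "manifold":
        if stimulus.pulses:
            raise ValueError(
                "the manifold form has a frozen index Q0 and cannot receive pulses; "
                "use form='qcoords' for stimulated runs"
            )
        Q0 = a
        t_eval = _output_grid(t0, t1, settings.dt, [])
        sol = solve_ivp(
            lambda t, y: rhs_manifold(t, y, Q0, params),
            (t0, t1),
            [b, c],
            method=settings.method,
            rtol=settings.rtol,
            atol=settings.atol,
            max_step=settings.max_step,
            t_eval=t_eval,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed on [{t0}, {t1}]: {sol.message}")
        return Trajectory(
            t=sol.t,
            Q=np.full_like(sol.t, Q0),
            qM=sol.y[0],
            iL=sol.y[1],
            params=params,
            stimulus=stimulus,
        )

    rhs = rhs_full if form == "full" else rhs_qcoords
    edges = [e for e in stimulus.edges() if t0 < e < t1]
    breakpoints = [t0, *edges, t1]
    t_eval = _output_grid(t0, t1, settings.dt, edges)

    y = np.array([a, b, c])
    ts_parts: list[np.ndarray] = []
    ys_parts: list[np.ndarray] = []
    for i, (seg_a, seg_b) in enumerate(zip(breakpoints, breakpoints[1:])):
        Is_val = float(stimulus.current(0.5 * (seg_a + seg_b)))
        # breakpoints are members of t_eval, so every segment has >= 2 samples
        seg_eval = t_eval[(t_eval >= seg_a) & (t_eval <= seg_b)]
        sol = solve_ivp(
            lambda t, yy: rhs(t, yy, Is_val, params),
            (seg_a, seg_b),
            y,
            method=settings.method,
            rtol=settings.rtol,
            atol=settings.atol,
            max_step=settings.max_step,
            t_eval=seg_eval,
        )
        if not sol.success:
            raise RuntimeError(
                f"integration failed on segment [{seg_a}, {seg_b}] "
                f"(Is={Is_val}): {sol.message}"
            )
        y = sol.y[:, -1]
        # drop the duplicated boundary sample from all but the first segment
        keep = slice(0, None) if i == 0 else slice(1, None)
        ts_parts.append(sol.t[keep])
        ys_parts.append(sol.y[:, keep])

    t = np.concatenate(ts_parts)
    ys = np.concatenate(ys_parts, axis=1)
    if form == "full":
        vC, qM, iL = ys
        Q = qM + params.C * vC
    else:
        Q, qM, iL = ys
    return Trajectory(t=t, Q=Q, qM=qM, iL=iL, params=params, stimulus=stimulus)


@dataclass(frozen=True)
class Outcome:
    """Asymptotic classification of a trajectory's trailing window."""

    kind: str  # "equilibrium" | "oscillation" | "undecided"
    value: float | None = None


def classify_outcome(traj: Trajectory, window: float, eps: float = 1e-6) -> Outcome:
    """Classify the trailing ``window`` of a trajectory.

    ``equilibrium`` (with the settled charge as value) if both ``|iL|``
    and the charge range stay below ``eps``; ``oscillation`` if ``iL``
    changes sign at least three times with amplitude above ``eps``;
    ``undecided`` otherwise.  The window must fit after the last pulse.
    """
    t_end = traj.t[-1]
    last_edge = max((e for e in traj.stimulus.edges()), default=traj.t[0])
    if t_end - max(last_edge, traj.t[0]) < window:
        raise ValueError(
            f"trajectory covers only {t_end - max(last_edge, traj.t[0]):.3g} time "
            f"units after the last pulse; window={window} requested"
        )
    mask = traj.t >= t_end - window
    iL = traj.iL[mask]
    qM = traj.qM[mask]
    if np.max(np.abs(iL)) < eps and (qM.max() - qM.min()) < eps:
        return Outcome("equilibrium", float(qM.mean()))
    signs = np.sign(iL)
    signs = signs[signs != 0]
    changes = int(np.count_nonzero(np.diff(signs) != 0))
    if changes >= 3 and np.max(np.abs(iL)) > eps:
        return Outcome("oscillation")
    return Outcome("undecided")


@dataclass(frozen=True)
class CycleEstimate:
    """Limit-cycle period and charge extrema measured from a trajectory."""

    period: float
    qM_min: float
    qM_max: float
    n_cycles_used: int
    transient_discarded: float


def extract_cycle(traj: Trajectory, discard_fraction: float = 0.5) -> CycleEstimate:
    """Estimate the limit cycle from the trailing part of a trajectory.

    The first ``discard_fraction`` of the time span is discarded as
    transient.  The period is the mean spacing of upward zero-crossings of
    ``iL`` (linearly interpolated between samples); by the phase
    convention of the PLC these crossings coincide with charge minima.
    Raises if fewer than three crossings remain.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must lie in [0, 1)")
    t0, t_end = traj.t[0], traj.t[-1]
    cut = t0 + discard_fraction * (t_end - t0)
    mask = traj.t >= cut
    t = traj.t[mask]
    qM = traj.qM[mask]
    iL = traj.iL[mask]
    up = np.nonzero((iL[:-1] < 0) & (iL[1:] >= 0))[0]
    if up.size < 3:
        raise ValueError(
            f"only {up.size} upward zero-crossings of iL after the transient; "
            "need at least 3 to estimate a period"
        )
    crossings = t[up] - iL[up] * (t[up + 1] - t[up]) / (iL[up + 1] - iL[up])
    period = float(np.mean(np.diff(crossings)))
    return CycleEstimate(
        period=period,
        qM_min=float(qM.min()),
        qM_max=float(qM.max()),
        n_cycles_used=int(up.size - 1),
        transient_discarded=float(cut - t0),
    )


@dataclass(frozen=True)
class PLCComparison:
    """Closed-form PLC vs. numerically extracted cycle on one manifold.

    Extrema errors are normalized by the PLC amplitude ``B_hat``: near the
    threshold one charge extremum passes through zero, so a ratio to the
    extremum's own value would be ill-posed.
    """

    Q0: float
    plc: PLC
    cycle: CycleEstimate
    period_rel_err: float
    qM_min_err: float
    qM_max_err: float


def compare_plc(
    params: CircuitParams,
    Q0: float,
    settings: IntegrationSettings | None = None,
    discard_fraction: float = 0.5,
    t_end: float | None = None,
) -> PLCComparison:
    """Quantify PLC accuracy on ``M(Q0)`` against a converged simulation.

    Integrates the planar dynamics from a perturbed near-equilibrium start
    (offset half the predicted amplitude) for long enough that the slow
    spiral-out near the threshold has settled, then compares period and
    charge extrema.
    """
    plc = solve_plc(params, Q0)
    if plc is None:
        raise ValueError(f"no limit cycle is predicted on M({Q0})")
    if t_end is None:
        # linearized spiral-out rate at the unstable equilibrium
        rate = (params.s1 / (2.0 * params.L)) * (q_bar(params) ** 2 - Q0**2)
        t_end = max(80.0, 6.0 / rate + 12.0 * plc.period)
    start = (Q0, Q0 + 0.5 * plc.B_hat, 0.0)
    traj = integrate("manifold", start, EMPTY_STIMULUS, (0.0, t_end), params, settings)
    cycle = extract_cycle(traj, discard_fraction)
    pmin, pmax = plc_extrema(plc)
    return PLCComparison(
        Q0=Q0,
        plc=plc,
        cycle=cycle,
        period_rel_err=abs(cycle.period - plc.period) / plc.period,
        qM_min_err=abs(cycle.qM_min - pmin) / plc.B_hat,
        qM_max_err=abs(cycle.qM_max - pmax) / plc.B_hat,
    )
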