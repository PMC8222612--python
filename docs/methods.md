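# Methods

## The circuit and its state-space forms

The model is a normalized R–L–C circuit closed through an ideal
charge-controlled memristor and driven by an independent current source
`Is(t)`.  The memristor flux–charge characteristic is odd,
linear-plus-cubic:

    φ(q) = −s0·q + (s1/3)·q³,        s0 > R,  s1 > 0.

The natural state is `(vC, qM, iL)` (capacitor voltage, memristor charge,
inductor current):

    dvC/dt = (Is − iL)/C
    dqM/dt = iL
    diL/dt = (vC + (s0 − R)·iL − s1·qM²·iL)/L.

All quantities, including time, are dimensionless.  The constraint
`s0 > R` is enforced at parameter construction (not at use): every
downstream stability and design formula requires a real charge threshold
`q̄ = sqrt((s0 − R)/s1)`, so an invalid set should fail immediately and
loudly.  State containers are immutable value objects and conversions
between coordinate systems are explicit functions; this removes a whole
class of silent coordinate-convention bugs.

When `Is = 0`, the combination `Q = qM + C·vC` has zero time derivative:
the state space is foliated into planar invariant manifolds `M(Q0)`,
each labelled by the conserved index `Q0`.  The package therefore offers
three *equivalent* right-hand sides — the full form, the `(Q, qM, iL)`
form in which `dQ/dt = Is` exactly, and the planar restriction to one
manifold — and tests their pairwise consistency as algebraic identities
and as integrated trajectories.

## Attractors per manifold

The equilibrium of `M(Q0)` sits at `(qM, iL) = (Q0, 0)` with Jacobian

    J(Q0) = [[0, 1], [−1/(LC), (s1/L)(q̄² − Q0²)]].

The determinant `1/(LC)` is always positive (never a saddle), and the
trace changes sign at `|Q0| = q̄`: stable focus for `|Q0| > q̄`, unstable
focus for `|Q0| < q̄`, purely imaginary pair at the threshold.  Because
the manifold dynamics is planar and its sole equilibrium repels for
`|Q0| < q̄`, each such manifold carries a stable limit cycle.  The
transition at `|Q0| = q̄` is Hopf-like but is crossed by varying the
*initial conditions* (which set `Q0`), not a circuit parameter — a
"bifurcation without parameters".

Eigenvalues are computed from the closed-form quadratic (trace and
determinant) rather than a general solver, preserving the exact conjugate
structure; a numeric eigensolver serves as the cross-check in the tests.
Classification uses a dead-zone of half-width `1e-9·max(1, q̄)` around the
threshold, reported as `critical`/`boundary`: testing float equality with
a bifurcation point is meaningless, and the band makes the label
reproducible.  Attractor *uniqueness* per manifold is asserted only as a
tested property at the reference parameters, not as a theorem.

## Describing-function limit-cycle prediction

Eliminating `iL` turns the planar dynamics into the Lur'e feedback form
`qM = −L(D)·φ(qM) + L0(D)·Q0` with

    L(D)  = (D/L)/(D² + (R/L)D + 1/(LC)),
    L0(D) = (1/(LC))/(D² + (R/L)D + 1/(LC)),

where `L(s)` is exactly the admittance seen at the memristor terminals
(R, L and C in series — the independent circuit-theory oracle used in the
tests).  Under the first-order ansatz `qM = A + B·cos(ωt)` the cubic
nonlinearity is quasi-linearized by the describing-function gains

    N0(A,B) = −s0 + (s1/3)(A² + (3/2)B²),
    N1(A,B) = −s0 + s1(A² + (1/4)B²),

which are identically the Fourier mean and first-cosine coefficient of
`φ(A + B cos t)`; a ≥1024-point uniform quadrature oracle verifies this to
1e−8 (the cubic contains only harmonics 0–3, so a uniform grid is
spectrally exact and 4096 points are far beyond sufficient).  Harmonic
balance (`A + L(0)N0A = L0(0)Q0`, `1 + L(jω)N1 = 0`) then yields the
Predicted Limit Cycle (PLC) in closed form:

    A = Q0,  ω = 1/sqrt(LC),  B² = 4(q̄² − Q0²),   |Q0| < q̄,

an exact ellipse `(qM − Q0)² + LC·iL² = B²` in the phase plane, with
charge extrema `Q0 ∓ 2·sqrt(q̄² − Q0²)`.  `solve_plc` returns a typed
`None` (not an exception) outside the existence region, including the
degenerate boundary within the tolerance band, because callers routinely
sweep `Q0` grids.  Higher harmonics are not represented symbolically; the
filtering hypothesis is validated numerically by comparing the PLC with
converged simulated cycles (at the reference parameters the period error
is ≲0.1% and the extrema errors ≲0.2% of the amplitude, far inside the
5%/10% acceptance bands).

In `compare_plc`, "relative extrema error" is normalized by the PLC
amplitude `B̂`, not by the extremum's own value: as `|Q0| → q̄` one
extremum passes through zero and a self-relative ratio would blow up on
an otherwise excellent approximation.

## Pulse-programmed spiking

A source pulse of area `Λ` and width `Δ` moves the trajectory from
`M(Q0)` to `M(Q0 + Λ)`; with rectangular pulses the index ramps linearly
during the pulse.  For small `Δ` the charge stays `O(Δ)`-close to its
pre-pulse value while `iL` acquires an `O(Δ)` kick (tested empirically by
halving `Δ` over `{0.1, 0.05, 0.025}·T`; the Taylor coefficients are not
computed symbolically).

A spike is the concatenation rest → oscillation window (n periods) →
rest, driven by a set pulse `(+Λ, Δ)` at the stimulus time `t_i` and a
reset pulse `(−Λ, Δ)` at `t_i + Δ + nT`.  Demanding that the post-pulse
state `(≈Q0_init, ≈0)` coincide with the minimum of the target manifold's
PLC gives the matching condition `Q0_init = Q0 − 2·sqrt(q̄² − Q0²)`; among
its many solutions the design takes the minimal `Q0_init` (found in
closed form at `Q0 = −q̄/√5`), which keeps the resting equilibrium as far
as possible from the critical manifold and is therefore maximally robust
to spurious small pulses.  The resulting quadruple is

    T = 2π·sqrt(LC),  Q0_init = −√5·q̄,  Λ = (4/√5)·q̄,  Δ = 2σπ·sqrt(LC),

with `σ = Δ/T ∈ [0.01, 0.05]` (default 0.02; out-of-range values warn
rather than fail because the width rule is a heuristic).  The predicted
waveform is piecewise: constant at `Q0_init` outside the window and
`Q0_target + B·cos(ω(t − t_i − Δ) + π)` inside, the phase `π` being the
unique choice that starts the oscillation at the PLC minimum and makes
the waveform continuous at the window edges; its derivative `iL0` is
defined one-sidedly at the edges (where it is zero anyway under this
phase).  Only rectangular pulses are generated; the pulse type carries a
`shape` field for future area-equivalent shapes but none ship.  Pulse
timing is an *input* here: no stimulus-detection or logic-level timer
hardware is modelled.

## Numerical choices

* Integrator: `scipy.integrate.solve_ivp` with DOP853, `rtol=1e−9`,
  `atol=1e−12`.  The dynamics is smooth and non-stiff at the reference
  parameters; the tight tolerances make conservation checks meaningful.
* Pulse edges are hard breakpoints — the solver is stopped and restarted
  with `Is` constant on each segment — so the delivered area is exact and
  never smeared by step control across a discontinuity.  Because
  Runge–Kutta methods preserve linear invariants, `Q` is conserved on
  source-free segments to roundoff (tests allow `100·atol`).
* Output is sampled on a uniform grid (default step 0.01) augmented with
  the exact edge times.
* Cycle extraction discards the first 50% of the span as transient by
  default, then takes the period as the mean spacing of upward
  zero-crossings of `iL` (linearly interpolated); the PLC phase
  convention puts `iL = 0` exactly at charge extrema, so crossings align
  with charge minima.  At least three crossings are required.
* `compare_plc` starts from the equilibrium perturbed by half the
  predicted amplitude and integrates for `max(80, 6/ρ + 12T)` time units,
  where `ρ = (s1/2L)(q̄² − Q0²)` is the linear spiral-out rate — near the
  threshold the escape from the unstable focus is slow and the horizon
  grows accordingly.  These horizons keep the full comparison sweep to a
  few seconds.
* Outcome classification over a trailing window: equilibrium if both
  `|iL|` and the charge range stay below `eps`; oscillation if `iL`
  changes sign ≥3 times with amplitude above `eps`; `undecided`
  otherwise.  Agreement tolerances used in the end-to-end tests (5% on
  period, 10% on extrema, 15% on spike-window extrema, 1% return-to-rest)
  are package choices: the underlying comparison is between an
  approximate analytic prediction and a converged simulation, and these
  bands are comfortably wide relative to the observed sub-percent errors.

## What the fixtures emulate — and what they do not

The fixture catalog packages the scenarios the package documents: the
reference parameter set `(R, L, C, s0, s1) = (0.4, 1.5, 0.1, 0.7, 0.3)`
(threshold exactly 1), a sub-threshold pulse (area 0.5) that hops between
two stable equilibria, a supra-threshold pulse (area 2.5) that lands on
an oscillatory manifold, the designed single spike (set at `t_i = 2`,
reset at 4.4821), and three 8-spike bursts (sets at t ∈ {10, 60, 110},
resets 19.5164 later).  All inputs are generated programmatically; there
is no external data.  These are idealized, noise-free normalized circuits:
passing tests demonstrate the internal consistency of the analysis and
simulation, not robustness to component tolerances, parasitics,
measurement noise, or non-cubic memristor characteristics — none of which
are modelled.  The design formulas themselves rest on two approximations
(small pulse width; PLC in place of the true cycle), and the end-to-end
simulations quantify exactly how much distortion those approximations
introduce at the reference parameters.

## Known limitations

* Only the odd linear+cubic memristor characteristic is supported.
* No Loeb-criterion or higher-order harmonic-balance machinery: PLC
  stability is argued from planar instability of the enclosed equilibrium
  and checked numerically.
* No continuation/bifurcation tooling and no chaos diagnostics (the
  circuit exhibits none at the reference parameters).
* The config seed field is reserved: the entire pipeline is
  deterministic, and identical configs produce byte-identical outputs.
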