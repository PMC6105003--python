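# Methods

## The model

`amyca` simulates a spatially homogeneous ("whole-cell") model of
intracellular calcium handling under a constant ambient amyloid-beta (Aβ)
level `a`.  Cytosolic calcium `c` (µM) exchanges with an endoplasmic
reticulum pool `c_e` through three ER pathways and with the extracellular
space through a leak and a pump:

    dc/dt   = J_IPR + J_RyR − J_SERCA + J_in − J_pm + J_vca
    dc_e/dt = −γ (J_IPR + J_RyR − J_SERCA)

with γ the cytosol/ER volume ratio.  Summing the two equations (after
dividing the second by γ) cancels every ER term, so the total cell calcium
`c + c_e/γ` changes only through the membrane fluxes — an exact identity
that the test suite asserts along trajectories and that the equilibrium
machinery exploits (see below).

The individual fluxes:

- **IPR** — `(k_f·P0 + J_er)(c_e − c)`, with open probability
  `P0 = (0.1·O + 0.9·A)^4` from a six-state receptor gating model
  (resting R, open O, active A, shut S, inactive I1/I2) whose transition
  rates saturate in `c` and are linear in IP3 `p` for the R→O binding
  step (Sneyd–Dufour type-2 receptor kinetics).  S is eliminated by the
  simplex constraint, leaving five gating ODEs.  `J_er` defaults to 0:
  the RyR leak `k1` plays the baseline-leak role in the assembled model,
  but the parameter is exposed so the isolated IPR flux can be exercised
  with an explicit ER leak.
- **RyR (CICR)** — `k3(c, a)·(c_e − c)` with
  `k3 = k1 + k2·c³/((k_d + k_α·a)³ + c³)`: a sigmoidal calcium-induced
  calcium release rate whose half-activation point is shifted by Aβ
  through `k_α`.
- **SERCA** — bidirectional four-state pump reduction
  `(c − K1·c_e)/(K2 + K3·c + K4·c_e + K5·c·c_e)`, reversing exactly at
  `c = K1·c_e`.
- **Membrane leak** — `J_in = a1 + a2·p + k_β·a^m`: basal leak, an
  IP3-proportional component, and an Aβ-pore influx with cooperativity
  `m = 4`.
- **Plasma-membrane pump** — Hill extrusion `V_pm·c²/(K_pm² + c²)`.
- **VGCC** — `J_vca = −p_s·ḡ_caT·m_caT²·h_caT·(V − V_ca)`, a T-type
  calcium current scaled into flux units by `p_s`, which absorbs the
  charge/volume conversion and acts as the single membrane→calcium
  coupling knob (`p_s = 0` decouples the compartments exactly).

Three variants are studied: `constant_ip3` (IP3 clamped, 7 ODEs),
`dynamic_ip3` (adds a hybrid PLC production/degradation equation for `p`
with Aβ entering both the maximal rate, `v_PLC + μ_PLC·a`, and the
sensitivity, `k_PLC + κ_PLC·a`; 8 ODEs), and `with_membrane` (adds a
Hodgkin–Huxley style voltage compartment with inward-rectifier K⁺, Na⁺,
delayed-rectifier K⁺, leak, and T-type Ca²⁺ currents; 13 ODEs).

The IP3 production denominator is implemented in two forms behind
`Ip3Params.squared_sensitivity`: `(k_PLC + κ_PLC·a)²` (the default,
consistent with the uncoupled PLC model, where the sensitivity constant
enters squared) and the linear alternative.  At `a = 0` the two coincide
because `k_PLC = 1 µM`; over the full Aβ range they shift the Hopf loci by
well under one percent, so the choice is not critical for any reported
quantity.

## Parameters

Defaults are the literature values of the calcium core (`k_f = 0.98 s⁻¹`,
`γ = 5.4`, RyR `k1 = 0.013`, `k2 = 0.18 s⁻¹`, `k_d = 0.13 µM`,
`k_α = 0.75`, SERCA `K1…K5`, leak `a1 = 0.003 µM s⁻¹`, `a2 = 0.02 s⁻¹`,
pore `k_β = 1 s⁻¹`, `m = 4`, pump `V_pm = 2.8 µM s⁻¹`,
`K_pm = 0.425 µM`) and of the PLC module (`v_PLC = 1.5 µM s⁻¹`,
`k_PLC = 1 µM`, `k_3K = 0.5 s⁻¹`, `k_5P = 0.25 s⁻¹`, `K_3K = 0.4 µM`,
`μ_PLC = κ_PLC = 1`).  The derived constants `τ_p = 1/(k_3K + k_5P)` and
`η = k_3K/(k_3K + k_5P)` are always recomputed, never set.

The IPR gating constants are the published calibration of the six-state
receptor (`k1 = 0.64 µM⁻¹s⁻¹ … l6 = 4707 s⁻¹`); every one of them is an
explicit `IprParams` field so an alternative receptor calibration can be
dropped in from configuration without touching solver code.

The membrane block needs constants beyond the calcium tables.  The
printed resting gating values (`m = 0.05`, `n = 0.32`, `h = 0.6` at
`V = −65 mV`) are the classical Hodgkin–Huxley resting state, so the
classical HH conductances, reversals and rate functions are adopted as
defaults, with the delayed-rectifier current switchable
(`include_ik`).  Two deliberate scalings make the block an *effective*,
qualitative model: rate constants are interpreted per second (not per
millisecond), putting the voltage response on the multi-second timescale
of the calcium dynamics and producing the saturating depolarised plateau
under sustained current injection that motivates the design; and the
tabulated Kir conductance (60) is scaled by `g_kir_scale = 1e-3` onto the
HH conductance scale so the unstimulated membrane rests within a few mV
of −65.  Membrane results should therefore be read qualitatively; the
calcium-side results (all with `p_s = 0`) do not depend on them.

## Equilibria and continuation

At any equilibrium with `p_s = 0` the total-calcium identity forces
`J_in = J_pm`.  This gives the equilibrium cytosolic calcium in closed
form for clamped IP3, `c* = K_pm·sqrt(J_in/(V_pm − J_in))`, and as a
scalar root (bracketed, Brent) for the dynamic variant, where `p` is
itself at its calcium-dependent fixed point.  The gating block then
follows algebraically as the stationary distribution of the six-state
generator (a linear solve), and `c_e*` from a second scalar root of the
ER balance.  A Newton polish on the full right-hand side (exact,
symbolically derived Jacobian) drives the residual below 1e-10.  Because
each equilibrium is constructed directly, natural-parameter continuation
needs no warm starting and cannot lose the branch at folds in parameter
ranges where the construction succeeds.

Existence has a sharp boundary: `J_in ≥ V_pm` (or loss of the coupled
scalar root) means the pump can no longer balance the influx and the
branch diverges.  Continuation refines that boundary by bisection; for
the clamped variant it coincides with the analytic root of
`a1 + a2·p + k_β·a⁴ = V_pm`.

Stability is read from the spectrum of the Jacobian.  The default
`eigenvalues_at` uses central finite differences with per-variable scaled
steps; the symbolically compiled Jacobian serves as an independent
cross-check (they agree to ~1e-5 relative in tests) and as the fast path
inside scans.  Bifurcations are detected from changes of the
unstable-eigenvalue count `n_u` between grid points, bisected to 1e-8 in
the parameter: a change of two through a conjugate pair with
`|Im λ| > 1e-3` is a Hopf point; a change of one through a real
eigenvalue a fold.  Counting `n_u` rather than tracking "the" critical
pair avoids a classic false positive: two already-unstable real
eigenvalues merging into a complex pair changes the leading complex real
part discontinuously but is not a bifurcation.

## Periodic orbits, Floquet multipliers, period doubling

Orbits are located by single shooting on a Poincaré section: `c` is
pinned at a reference level (the mid-range of a converged oscillatory
trace) with increasing orientation, and a damped Newton iteration (with
backtracking line search on the flow residual) adjusts the remaining
state components and the period until the orbit closes; closure below
1e-9 in state norm is achieved away from bifurcations, and continuation
work accepts 1e-7 (above the variational integration error floor, far
below the 1e-6 closure contract).  The monodromy matrix is integrated
alongside the trajectory (variational equations with the exact Jacobian);
its eigenvalues are the Floquet multipliers.  Two certificates accompany
every orbit: the residual, and the trivial multiplier, which must equal
+1 to 1e-3.  For strongly contracting orbits the smallest multipliers sit
at the numerical noise floor (the monodromy condition number is large by
nature); they are reported but only their magnitudes being below one is
meaningful.

Period doubling is tracked with the most negative real multiplier.  That
choice matters: past a PD point the critical multiplier runs away towards
large negative values quickly, so "the multiplier nearest −1" stops
identifying it almost immediately.  The orbit branch is continued with
warm-started shooting and an adaptive parameter step that halves whenever
shooting fails or the period jumps by more than 25% (the sign that the
solver slipped onto the doubled attractor); each crossing of −1 is
bisected to 1e-3.  During bisection a hard shooting failure is treated as
the post-PD side — near the first PD the primary orbit is mildly unstable
and solvable, and failures occur only where the instability is already
strong.

## Trace classification

A post-transient window (default: drop the first 40% of the trace,
analyse 200 s) is labelled `steady`, `periodic`, `mmo`, or `aberrant`.
Peaks are detected by prominence (5% of the window range, floored at
0.01 µM) after a 0.25 s moving-average smoothing whose only role is to
keep measurement noise from seeding spurious peaks.  Peak amplitudes are
clustered by a deterministic one-dimensional gap rule (a sorted gap above
20% of the maximum amplitude opens a new class), and periodicity is
scored as the best lag-wise agreement of the (amplitude class,
inter-peak interval) cycle sequence — 1.0 for a perfectly repeating
pattern.  A trace is `steady` below 0.005 µM of residual variation or
with fewer than three peaks; `periodic`/`mmo` when the score reaches 0.9
with one/multiple amplitude classes; `aberrant` when it oscillates (≥ 5
peaks) without a repeating cycle.  All thresholds live in
`ClassifyOptions`; classification is bit-for-bit reproducible and
invariant to amplitude rescaling and time shifts.

Regime surveys (`classify_parameter_grid`) integrate 900 s per grid point
so that the default transient cut discards at least 300 s: near regime
boundaries the attractor is approached slowly, and classifying residual
transients would blur the MMO/aberrant boundary.

The synthetic labelled waveforms (`amyca.cli_io.synth_waveform`,
`generate_fixtures`) are Gaussian-bump spike trains on a flat baseline:
one amplitude at a fixed interval (`periodic`), a repeating
one-large/three-small cycle (`mmo`), seeded irregular draws of amplitude
and interval (`aberrant`).  They emulate the *geometry* the classifier
keys on — amplitude classes and cycle repetition — not the model's spike
shapes, baselines, or slow drifts; classifier accuracy on them
demonstrates that the decision rules implement the intended taxonomy,
not that the thresholds are optimal for noisy experimental recordings.

## Numerical choices

- Integration: adaptive explicit Runge–Kutta (4,5) by default at
  `rtol 1e-8`/`atol 1e-10`, dense output resampled at the configured
  step; LSODA/BDF/Radau selectable per run for stiff legs (the gating
  block carries ~30 s⁻¹ rates next to ~100 s calcium cycles).  Stimulus
  boxcars split the integration at the pulse edges so the discontinuity
  never falls inside an adaptive step.
- The right-hand side is written once over the pure flux/gating
  functions and evaluated either numerically or symbolically; sympy
  compiles per-variant scalar callables (with common-subexpression
  elimination) for the trajectory, Jacobian, and variational systems.
  Unit tests pin the compiled path to the direct composition at 1e-12.
- Transiently negative concentrations probed by the integrator inside a
  rejected step are clamped to zero inside flux evaluation only; stored
  states are never modified.
- Degenerate inputs: non-finite fluxes abort with the offending term
  named; traces too short or non-uniformly sampled for classification
  are rejected with the required minimums in the message.

## Problem sizes

The bundled analyses run at desk scale: equilibrium scans use 67–131
continuation points (bisection refines detected points to 1e-8 so the
grid density only needs to separate bifurcations); the period-doubling
search continues the orbit branch from `k_α = 0.3` with initial step
0.05 and bisects to 1e-3 (~3 minutes); trajectory-based checks use
400–900 s horizons.  Halving scan steps or solver tolerances moves the
reported bifurcation values by less than 1e-3 (asserted in tests).

## Known limitations

- Under the default parameter set the dynamic-IP3 variant has a unique
  low-calcium equilibrium for small `a`: since equilibrium requires
  `J_in = J_pm` and the PLC fixed point is bounded by
  `p* ≤ 3·(v_PLC + a)`, the amyloid-free steady state sits at
  `c* ≈ 0.014 µM` with `p* ≈ 0.02 µM` — too little IP3 to engage the
  receptor, so the variant's oscillatory structure in `a` consists of a
  single Hopf window (≈ 1.10–1.26) adjacent to the terminal divergence
  (≈ 1.29), both inherited from the Aβ-pore influx term rather than from
  IP3 dynamics.
- The membrane compartment is qualitative (see above); quantitative
  claims should be restricted to `p_s = 0` configurations.
- Orbit continuation degrades to simulation-based characterisation
  inside MMO windows where single shooting on the primary branch stops
  converging; results there carry `method="simulation"` and no Floquet
  certificate.
- No spatial resolution, explicit buffering, mitochondria, or time
  evolution of the Aβ level; `a` is a constant environmental parameter.
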