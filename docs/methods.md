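# Methods

This note documents the model as implemented, the choices made where the
published description is silent or self-inconsistent, and what the test
suite does and does not establish.

## Model structure

Two subsystems are coupled one-way: the store-excitation subsystem
(x₁…x₅, no voltage dependence) drives the membrane subsystem (Cl⁻ gate y
and PD V) through the Ca²⁺ signal.  There is no feedback from V to Ca²⁺
unless the TRP conductance G_Ca is enabled, and by default it is not — the
plasma-membrane Ca²⁺ pulse acts only through the ΔCa²⁺ offset.

State vector of `simulate_ap`: [x₁, x₂, x₃, x₄, x₅, y, V] with V in volts
internally; all interfaces speak mV, µM and mM (mM ≡ mol·m⁻³).

## The excess-calcium convention (the one substantive design choice)

The store-pump Hill term and the Cl⁻-gate drive both act on the Ca²⁺
*elevation above rest*, δ = max(x₁ − x₁_rest, 0), with
x₁_rest = [Ca²⁺]_cyt,rest/C₀ = 0.02/1.56 ≈ 0.0128, rather than on total x₁.
Reasons:

1. **Baseline consistency.**  The fitted pump half-saturation p₂′ ≈ 0.02 µM
   coincides with the resting Ca²⁺ concentration.  A Michaelis–Menten pump
   (n = 1) on total Ca²⁺ would run at half its maximal rate *at rest* and
   pull resting Ca²⁺ ~50× below the stated resting concentration; the
   stated initial state would not be a baseline at all.
2. **Excitability.**  With the pump on total x₁, its slope at the origin is
   p₁/p₂ ≈ 500 s⁻¹ and every n = 1 parameter column is inexcitable: the
   printed ΔCa²⁺ pulses (0.004–0.03) are an order of magnitude below the
   ignition threshold (verified numerically with an independent fixed-step
   integrator).  With the excess-Ca²⁺ pump, every bundled column ignites
   and the stimulus threshold behaves correctly (1% of the IP₃ bolus
   produces no AP).
3. **Gate at rest.**  The Cl⁻-channel rate constants describe activation by
   *increased* cytoplasmic Ca²⁺.  Driven by total x₁, the gate would rest
   at y ≈ 0.03, and the saline-condition columns with G_Cl,max = 80 S·m⁻²
   would carry ~0.8 A·m⁻² of resting Cl⁻ current — incompatible with their
   measured resting PDs by tens of mV.

Biophysically this is a homeostasis statement: basal Ca²⁺ is maintained by
fluxes outside the model, and the store pump and Cl⁻ channels respond to
the excitation-driven elevation.  At Ca²⁺ levels reached during an AP
(x₁ ≈ 0.5–0.9) the excess and total formulations differ by < 2%.

## ΔCa²⁺ pulse semantics

The pulse is a constant additive offset to x₁, applied only inside its
window and fed to every consumer of x₁ — the release and pump terms, the
store-channel binding steps (Eqs. for x₂…x₅), and the Cl⁻ gate.  The
integration is split at the window edges (and at every schedule
breakpoint) so no discontinuity sits inside a solver step.  An alternative
"extra term in dx₁/dt" reading was evaluated and rejected: with any natural
normalization the injected Ca²⁺ is too small to matter.

## Schedules

* **κ_oi ramp** (transient H⁺-pump inhibition by high cytoplasmic Ca²⁺,
  then recovery): piecewise linear, constant before t_start = 2.75 s,
  linear to an end value at t_stop = 10.5 s (the published fits give only
  the ranges 0.5–5 s and 9–12 s; defaults sit mid-range).  The end value is
  not printed anywhere; the registry derives it by solving
  resting_pd(κ_oi) = printed post-excitation PD — the same calibration used
  to set the starting κ_oi from the pre-excitation PD.  Columns whose pre-
  and post-PDs agree within 1 mV get no ramp.  An optional linear recovery
  leg (duration default 2 s) is available but not used by the registry,
  since a single end value already reproduces the post-AP level.
* **G_Cl,max decay**: G_end + (G_start − G_end)e^(−t/τ) for the first 5 s,
  G_end after; τ = 1 s (not stated; configurable).  Used by the one column
  that prints a conductance range ("20–4.1").

## Numerical choices

* Adaptive integration: LSODA, rtol 10⁻⁸, atol 10⁻¹⁰ (fitting uses 10⁻⁶ /
  10⁻⁹ for speed; the difference is ≪ instrument noise).  State is never
  clipped inside the solver; the gate open fraction is clamped to [0, 1]
  only where it enters rates.
* The resting PD is found by bisection on [−300, −40] mV to 0.01 mV; a
  missing sign change raises an error naming the bracket and endpoint
  currents.
* The GHK rectifier's removable singularity at V = 0 is evaluated through
  `expm1` with an analytic-limit branch at |u| < 10⁻¹²; continuity was
  verified to 10⁻⁹ relative at ±10⁻⁹ mV.
* Physical constants: T = 293 K, RT/F ≈ 25.25 mV.  C_m is never printed;
  0.01 F·m⁻² (typical characean plasma membrane) is the default, exposed
  as a parameter.  V₅₀₋ of the rectifier is never printed; +300 mV keeps
  the P_o₋ closure far above the physiological range so P_o₋ ≈ 1 there
  (note the printed Boltzmann form makes P_o₋ → 1 for V *below* V₅₀₋).
* `fixed_step_rk4` is an independent classical RK4 oracle sharing only the
  RHS with the adaptive path; oracle agreement on the average-fit AP over
  20 s is 4×10⁻⁵ in x₁ sup-norm and 3×10⁻⁴ mV in V at dt = 10⁻⁴ s.

## Fitting

Local bounded least squares (`scipy.optimize.least_squares`, trust-region
reflective) on full-trace RMSE in mV, from a user-supplied start —
mirroring the manual tuning that produced the bundled columns; no global
search is claimed.  A start whose RMSE is already below 0.01 mV (far below
instrument noise) is returned as converged.  Query points that fail to
simulate receive a large penalty residual instead of aborting.
`loss_profile` exposes 1-D loss sweeps so weakly identified directions
(e.g. the p₂′ / k₋₃ trade-off) are visible rather than silently resolved.

## Synthetic data

`generate_population` draws per-cell parameters from mean-preserving
lognormal distributions (positive rates; CV default 0.1 on p₁′, p₂′, k₋₃,
I₀, G_Cl,max), adds i.i.d. Gaussian voltage noise (default 1 mV at 10 ms
sampling), and optionally concatenates APs into repetitive-AP trains.
Defaults emulate the observed freshwater variability: six cells, peaks
spread around −29…−4 mV, resting PDs −260…−60 mV across conditions.  What
it does **not** emulate: electrode drift, impalement artifacts, the
stimulation-current ramp, correlated noise, or genuine tonoplast dynamics
(tonoplast APs exist here only as constructed trace arithmetic).  A green
pipeline test therefore establishes internal consistency of
generation → averaging → fitting, not field validity of the noise model.

Because the model is genuinely near-threshold, a lognormal draw can
produce a non-firing cell (e.g. p₁′ ~20% above the average-fit value
quenches ignition); such traces are kept, as in a real recording session.

## Known limitations

* The simulated average-fit AP has a half-amplitude width of ~8.0 s,
  slightly above the 4–7 s envelope of individual measured APs.  The
  average-fit column describes the *ensemble-average* AP, which is smeared
  wider than any individual AP; within this package no printed parameter
  value was altered to force the width down.
* The strongest-pump saline column (κ_oi = 950 s⁻¹, G_Cl,max = 80 S·m⁻²)
  does not reach a full AP under this reading; its pump current dominates
  every other term at all physiological PDs.
* Depolarized pump-off resting PDs (−68…−120 mV) are measured values, not
  model steady states (the background current alone rests at −100 mV);
  simulations therefore start from the tabulated V₀ rather than from the
  zero-current root.
* Single-compartment, spatially uniform; no Ca²⁺ diffusion, no pH/H⁺
  chemistry, no Na⁺ transport, no emergent repetitive firing (trains are
  composed, not spontaneous).
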