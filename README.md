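# characean-ap

Simulation and analysis of the **characean action potential (AP)** — the
electrical excitation of giant internodal cells of charophyte algae
(*Nitellopsis*, *Chara*), including its response to osmotic and saline
stress.  The package is a library: its public face is the importable API
plus the narrative scripts in `examples/`.

## The model

Excitation is driven by second messengers.  A bolus of IP₃ (decaying as
*I = I₀e^(−0.2t)*) gates a four-state Ca²⁺ channel on internal stores —
unbound (R), IP₃-bound (RI), conducting (RIC₊), Ca²⁺-inactivated
(RIC₊C₋), fractions x₂…x₅ with Σx = 1:

```
dx2/dt = −k1·I·x2 + k−1·x3
dx3/dt =  k1·I·x2 − (k−1 + k2·x1)·x3 + k−2·x4
dx4/dt =  k2·x1·x3 + k−3·x5 − (k−2 + k3·x1)·x4
dx5/dt =  k3·x1·x4 − k−3·x5
```

Scaled cytoplasmic Ca²⁺, x₁ = C/C₀, rises through store release and falls
through a Hill-type store pump acting on the elevation δ above the resting
level (see `docs/methods.md` for why δ and not total C):

```
dx1/dt = λ(γ0 + γ1·x4)(1 − x1) − p1·δⁿ/(p2ⁿ + δⁿ),   δ = max(x1 − x1_rest, 0)
```

The Hill exponent n is 1 (Michaelis–Menten, gradual repolarization,
*Nitellopsis*) or 2 (cooperative, steep repolarization, *Chara*).  A brief
TRP-like Ca²⁺ pulse ΔCa²⁺ offsets x₁ inside a stated window to sharpen the
upstroke.

The membrane PD V then evolves under five currents (outward positive):

```
Cm·dV/dt = −[ I_Cl + I_p + I_orc + I_bkg + I_TRP ]
```

* `I_Cl = G_Cl,max·y·(V − E_Cl)` — Ca²⁺-activated Cl⁻ current, first-order
  gate `dy/dt = k_a·δ(1−y) − k_i·y`;
* `I_p` — H⁺-ATPase as charge transit over a symmetric Eyring barrier,
  `I_p = z_p F N (k_io κ_oi − k_oi κ_io)/(k_io + k_oi + κ_io + κ_oi)` with
  `k_io = k_io⁰ e^{z_pFV/2RT}`, `k_oi = k_oi⁰ e^{−z_pFV/2RT}`;
* `I_orc` — K⁺ outward rectifier: GHK constant-field flux × Boltzmann open
  probabilities P_o₊·P_o₋;
* `I_bkg = G_bkg(V − E_bkg)` — empirical leak;
* `I_TRP` — square-pulse Ca²⁺ inflow (off by default; the pulse acts
  through ΔCa²⁺).

A registry bundles the complete fitted parameter columns (freshwater,
sorbitol, 50/100 mM NaCl conditions for several cells); transient H⁺-pump
inhibition during the AP is represented as a piecewise-linear ramp of
κ_oi whose end value is calibrated against the printed post-excitation
resting PD.  On top sit trace analytics (AP features, ensemble averaging
with SD, tonoplast subtraction with quadrature error propagation),
bounded least-squares parameter fitting against the simulator, and a
seeded synthetic-recording generator.

## Worked example

```python
import characean_ap as ca

ps = ca.load_parameter_set(2, "AP_av Nitellopsis APW")
print(ca.resting_pd(ps))                 # zero-current membrane PD
res = ca.simulate_ap(ps, t_end=20.0, dt_out=0.01, t_pre=1.0)
f = ca.ap_features(res.trace, (-1.0, 0.0), (18.0, 20.0))
print(f.peak, f.half_width)
```

Running `examples/simulate_average_ap.py` prints:

```
zero-current resting PD :  -231.36 mV   (printed pre-AP value -234 mV)
AP peak                 :   -14.88 mV   (measured envelope -29 to -4 mV)
time of peak            :     2.23 s after the IP3 bolus
half-amplitude width    :     8.00 s
resting PD before/after :  -231.08 / -235.96 mV
peak Cl- current        :   -0.233 A m^-2 (inward, depolarizing)
peak K+ rectifier       :    0.038 A m^-2 (outward, repolarizing)
```

The resting PD is the root of the pump/leak/rectifier balance and lands
within a few mV of the measured pre-excitation value; the simulated AP
peaks inside the measured envelope; and the current table explains the
transient term by term.  The other examples cover the saline-stress
series, tonoplast subtraction, store-only Ca²⁺ dynamics, and a full
population-generation → averaging → fitting round trip.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at run time: the zero-current resting PDs of four
pump-parameter columns (bisection of the total resting current), and the
peak PD and half-amplitude width of the AP simulated from the average
freshwater fit column.  Results are written as JSON, one entry per target.
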