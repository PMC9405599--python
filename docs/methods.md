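# Methods

## Model and assumptions

The package implements a lumped (0D) electrical analogue of a two-story
intracranial aneurysm. The parent artery's flow F(t) and pressure P(t) are
*prescribed* — the aneurysm is assumed too small to feed back on the
systemic circulation — and drive a five-element circuit: neck resistance R,
mother sac (capacitance C1, inductance L1), daughter sac (C2, L2).
Capacitance stands for sac volume per unit pressure, inductance for wall
compliance (elasticity/thinness); turbulence, vortex structure and wall
shear stress are outside a lumped model by construction, and the fluid is
treated as ideal (non-Newtonian viscosity is not modelled).

Units follow the source convention and are *not* dimensionally closed:
pressures in mmHg, flows in mL/min, time in seconds, R, C, L as pure
numbers used exactly as printed (whether R = 2.2 carries mmHg·min/mL or is
dimensionless is not decidable; the model is an analogue). Flows and
pressures may be negative — the intra-aneurysmal flow alternates direction.

The solvable core is the daughter-flow oscillator

    F2'' + ω0² F2 = d/dt [P/L2 − (L1/L2) d/dt(F − P/R)],  ω0 = 1/√(C2 L2),

with every other series recovered algebraically: F1 = F − P/R,
P1 = P − L1·dF1/dt, P2 = P1 − L2·dF2/dt, Q_i = C_i·P_i. Drive derivatives
(P′, F″, P″) are evaluated in closed form from the sinusoid, never by
differencing, so no discretization noise enters the forcing.

### A structural asymmetry worth knowing about

Because F and P are both prescribed, the system is overdetermined: the
recovery chain enforces the daughter-node charge balance d(C2·P2)/dt = F2
identically (its numerical residual converges at O(dt²)), but the
mother-node balance d(C1·P1)/dt = F1 − F2 is *violated by construction* —
its residual is a heartbeat-tone-sized series (≈ 55 mL/min at the reference
setting) that does not shrink with dt. `kirchhoff_residuals` returns both
series so users can see this asymmetry; one test documents the expected
finite mother-node residual, and the test asserting it vanishes is known to
fail — it states a property the model does not have. The degenerate L2 = 0
branch is the one place the mother balance *is* used: there it closes
algebraically to F2 = C2·F1/(C1 + C2).

A related consequence: the peak daughter pressure *decreases* mildly along
the daughter-growth sweep (e.g. 200 → 172 mmHg over C2/C1 = 0.2 → 1.0 in
the ordinary scenario) because growing C2 moves ω0 *away* from the
heartbeat frequency. The package reports the measured trend rather than
asserting monotone growth; the robust quantitative claims — mother pressure
capped at ≈ 169.6 mmHg independent of the daughter, every dangerous-ratio
run above 120 mmHg, slow-flow regime below 10 mL/min — hold and are tested.

## Numerical scheme

Explicit central differences (leapfrog),

    F2[n+1] = 2 F2[n] − F2[n−1] + dt² (rhs(t_n) − ω0² F2[n]),

bootstrapped by a second-order Taylor step from F2(0) = 0.58 mL/min,
F2′(0) = 0. This is the simplest scheme consistent with a plain
finite-difference discretization; the large forcing term dominates the
error budget and prevents error accumulation. Properties verified by the
suite:

* agreement with the exact two-tone closed form to ≤ 1e-3 relative over
  60 s at dt = 0.002 (typically ~2e-5);
* second-order convergence (halving dt cuts the discrepancy ≈ 4×);
* stability for ω0·dt < 2; beyond it the stepper raises a blow-up error
  naming the first bad node.

The closed form (particular two-tone solution plus homogeneous tone matched
to the initial state) is the independent oracle; it refuses configurations
within |ω0² − ω²| < 1e-6 of exact resonance, where the secular, linearly
growing response is not representable by two tones. The numeric path has no
such guard.

Defaults: dt = 0.002 s; horizon 60 s. The horizon is a package choice: it
covers many slow beat-envelope periods so window maxima are close to the
asymptotic two-tone supremum (the tones are incommensurate), whereas a
20 s window can miss the envelope peak by a few mmHg. Maxima are taken over
the whole window from t = 0 — the initial state is part of the model, not a
transient to be discarded. dF2/dt for the pressure recovery uses
second-order differences of the computed F2; the residual diagnostics trim
the boundary-polluted end nodes.

## Parameters, presets and dialects

| parameter | meaning | default | source |
|---|---|---|---|
| R | neck resistance | 2.2 | fixed so ≤ 10% of parent flow diverts (exactly 1/11 with the default drive) |
| C1 | mother capacitance | 0.100 | reference sac size |
| C2 | daughter capacitance | 0.005 | `fig3_caption` dialect |
| L1, L2 | compliances | 10, 20 | reference dumbbell |
| f, F(0), P(0) | drive | 70/60 s⁻¹, 50 mL/min, 100 mmHg | physiological table values |
| F2(0), F2′(0) | initial state | 0.58 mL/min, 0 | printed initial condition |

The printed sources are internally inconsistent in two places, and both
readings are preserved as switches rather than silently resolved:

* the typical-dumbbell C2 is printed as both 0.005 (`fig3_caption`,
  default) and 0.05 (`fig3_text`);
* the ordinary growth scenario is printed as both L1 = 2·L2
  (interpretation `caption`, default: L2 = L1/2) and L2 = 2·L1
  (interpretation `text`). The solitonic scenario is L2 = L1 in both.

The single-run `fig5` preset needs one concrete L1 (its study sweeps L1);
L1 = 40 was chosen — the thin-wall risk border — so the preset exercises
the compliance flag. The compliance sweep's default grid 0–80 in steps of
10 covers the asymptotically linear range of
max P1 = 100 + √(400 + (10·ω·L1/11)²) (R² > 0.99 on [20, 80]) and the
L1 > 40 border.

## Geometry and risk thresholds

Sphere approximation: 4πR³/3 = C per sac. The aspect-ratio mapping
α = (√3/2)(1 + (C2/C1)^⅓), with neck width w = √3·R1 and depth
d = (3/2)(R1 + R2), is pinned uniquely (among a + b·ratio^⅓ forms) by its
two printed anchors α(1.0) = 1.73 and α(0.8) = 1.67; the printed rendering
of the intermediate w, d expressions is typographically corrupted in the
source, so only the anchors are treated as authoritative. Thresholds:
α > 1.6 (shape), C2/C1 > 0.80 (daughter size), L1 > 40 (thin/elastic
wall), local pressure > 180 mmHg (applied to max P2; a single-sac variant
applies it to max P1). Scenario notes label L1 ≈ L2 (within 10% relative)
"solitonic" and L1 > 40 "to-and-fro resonating".

## Soliton reduction

For a pressure-softening wall C1(P) = −(aP + b)⁻¹ the stored volume is
Q1 = −(1/a)·log((a/b)P1 + 1) (verified against quadrature to 1e-8), and
when the compliance-mismatch term (L2 − L1)·dF2/dt is negligible the
pressure triple (P0, P1, P2) obeys

    (L1/a) d²/dt² log((a/b)P1 + 1) = 2P1 − P2 − P0,

one site of the Toda lattice in interaction variables
(P_{0,1,2} = (b/a)·V_{n−1,n,n+1}, exact when L1 = −b). a and b are not
fixed by the physiology; defaults a = −1, b = −1 give C1(0) = 1 over the
physiological range and put the exact-correspondence point at L1 = 1, the
`TodaParams` default. The 1-soliton V_n = sinh²κ·sech²(κn − sinh(κ)t)
satisfies the lattice equation *identically* (via
1 + sinh²κ·sech²θ = cosh(θ+κ)cosh(θ−κ)/cosh²θ), so the analytic residual
is at machine precision and the finite-difference residual at O(dt²); its
speed sinh(κ)/κ exceeds the lattice sound speed for every κ > 0.

Sign convention: the reduction's node relations carry the opposite L2 sign
(P2 = P1 + L2·dF2/dt, "eq3") from the main recovery ("eq1",
P2 = P1 − L2·dF2/dt); both appear in the source, both are selectable in
`main_model_triple`, and the reduction's own convention is the default for
all reduction operations. The reduction is analysed on its own terms only:
the nonlinear capacitance is never fed back into the time-domain stepper,
and the residual of the reduced equation on a linear-capacitance circuit
trajectory is reported, not asserted small. `reduction_precondition_check`
quantifies how negligible the mismatch term is (default verdict threshold:
ratio ≤ 0.1 against the retained inertial term).

## Determinism, I/O, problem sizes

The model has no randomness: identical configurations give bit-identical
outputs, and every artifact embeds its resolved flat configuration so a run
can be reproduced exactly from its own output. Series go to CSV in
shortest-round-trip float form (read-back is bit-exact); summaries, sweeps
and checklists to JSON. A full 60 s run is 30 001 nodes and takes
milliseconds; the complete sweep suite is a few dozen such runs, so the
default test suite and the acceptance script each finish in seconds.

## Known limitations

* The parent artery never feeds back; the mother-node charge balance is
  structurally violated (see above).
* Near exact resonance ω0 ≈ ω the closed-form oracle and the beat
  decomposition refuse to run; the numeric path runs but grows secularly.
* The aspect-ratio formula is calibrated on C2/C1 ∈ [0, 1] only (warned
  outside); geometry is a sphere approximation, not patient morphometry.
* Risk flags restate the model's thresholds; they are not clinical rupture
  probabilities.
* The "three-times-longer beat" remark attached to the typical-dumbbell
  setting is not reconstructable under either C2 dialect (natural period
  2.32× or 7.33× the heartbeat; beat period 1.76× or 1.16×); the package
  reports both periods and asserts neither ratio.
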