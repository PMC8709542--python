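# Methods

## The model

`fhncircuit` analyses a two-variable neuron model written in electrical
units: a membrane voltage *u* (V) and a slow recovery current *w* (A)
driven by an applied current *I* (A),

    C_m du/dt = I − (1/R_I) (u³/(3u₁²) − u) − w
    τ_k dw/dt = u/R_w − b w

with six independent parameters, all strictly positive:

| parameter | meaning | unit | typical |
|---|---|---|---|
| τ_m | membrane (voltage) response time | s | 10⁻² |
| τ_k | recovery response time | s | 10⁻²…10 |
| R_I | channel resistor | Ω | 0.5 |
| R_w | recovery resistor | Ω | ~0.5 |
| b | recovery modulation constant | — | ~1 |
| u₁ | reference voltage | V | 1 |

Derived quantities: ε = τ_m/τ_k (time-scale ratio; excitable-membrane
operation means ε ≪ 1), r = R_I/R_w, C_m = τ_m/R_I, L = τ_k·R_w.  The
built-in presets A–F share R_I = 0.5 Ω, τ_m = 10⁻² s, u₁ = 1 V and span
(b, r, ε) combinations from the fast-recovery regime (ε > 1, models A
and B — included for completeness although they invert the physical
time-scale ordering) through moderately slow (C, ε = 0.316) to the
relaxation-oscillation regime (D–F, ε = 0.01).

The stationary curve is I(u) = (1/R_I)(u³/(3u₁²) − u) + u/(bR_w), odd in
u.  For r/b < 1 it is three-valued around the origin: the fixed points of
a drive are the one-to-three real roots of the cubic, found in closed
form (trigonometric/Cardano for the depressed cubic) with a Newton
polish, merging roots closer than 10⁻⁹·u₁ (saddle-node tangency).

## Linear analysis

The Jacobian trace and determinant are reported dimensionless —
trace_norm = tr J·τ_m = (1 − u²/u₁²) − εb, det_norm = det J·τ_m² =
ε[b(u²/u₁² − 1) + r] — so the bifurcation conditions read off directly:

* Hopf at trace_norm = 0: u_H = u₁√(1 − εb), present iff εb < 1.  The
  implementation locates u_H by a bracketed root solve of trace_norm on
  (0, u₁) rather than the closed form, so it survives modifications of
  the nonlinearity; the closed form serves as the test oracle.
* Saddle-node at det_norm = 0 (equivalently dI/du = 0):
  u_SN = u₁√(1 − r/b), present iff r/b < 1.
* Pitchfork of the I = 0 fixed-point set at r = b.

Classification uses det < 0 ⇒ saddle; det > 0 with tr ≶ 0 ⇒
(un)stable, spiral iff tr² − 4·det < 0.  Non-hyperbolic boundaries are
flagged at |trace_norm| < 10⁻⁹ or |det_norm| < 10⁻¹², several orders
below the 10⁻⁴ precision of the tabulated anchors.

## Equivalent circuit and impedance

Linearization + Laplace transform give three parallel branches: C_m, a
bias-dependent channel conductance G_b = (u²/u₁² − 1)/R_I (negative in
the NDR window |u| < u₁), and the recovery branch R_a = bR_w in series
with a chemical inductor L = τ_k·R_w.  Z(iω) = 1/(iωC_m + G_b +
1/(R_a + iωL)); Z(0) = R_dc = 1/(G_b + 1/R_a) equals the reciprocal
stationary-curve slope, and all spectra end at the origin as ω → ∞.

The admittance numerator s²C_mL + s(C_mR_a + LG_b) + (R_aG_b + 1) is,
up to the factor C_mL, the characteristic polynomial of the Jacobian:
its roots *are* the eigenvalues.  Under constant-current drive these are
the poles of Z, so the Hopf bifurcation appears on the spectrum as a
purely imaginary impedance pole at ω = √(det J) — the galvanostatic form
of the Nyquist stability criterion.  (It is a pole, not a zero: |Z| → ∞
and |Y| → 0 on the real-frequency axis at the Hopf bias.)

### Regime classification

Crossings are located by sign change on a 60-points-per-decade scan of
[10⁻³/τ_k, 10³/τ_m] rad/s (extended upward in decades until the
high-frequency Re-asymptote is reached) plus bisection.  The cascade:

1. **NEGATIVE_RDC** — dc conductance G_b + 1/R_a < 0.
2. **HIDDEN_NDR** — R_dc > 0 and the spectrum crosses into Re Z < 0
   through the fourth quadrant of the −Im Z plot (Im Z > 0 at the
   crossing).  Note Re Z < 0 at high frequency happens at *every* bias
   inside the NDR window (Re Y → G_b < 0); the crossing *direction* is
   what marks instability: at the frequency ω_c where Re Y = 0,
   Im Y(ω_c) = ω_c(C_m + G_bL/R_a) is negative iff tr J > 0.  So
   HIDDEN_NDR labels exactly the spiking (unstable-focus) biases.
3. **INDUCTIVE_LOOP** — stable bias whose Im Z crosses zero at finite
   frequency.  The exact crossing condition is κ ≡ L/(R_a²C_m) =
   (r/b²)/ε > 1, which reduces to the familiar loop condition
   τ_k > R_aC_m (ε < r/b) at b = 1 — the case of all the positive-R_dc
   presets; for b ≠ 1 the two differ at second order and the code uses
   the spectrum itself.
4. **BENT_ARC** — no crossing but κ ≥ 0.5: the inductive branch cancels
   at least half of the low-frequency capacitive susceptance
   (Im Y = ωC_m(1 − κ) + O(ω³)), visibly flattening the arc against the
   real axis.  The 0.5 threshold is a deliberate design choice: the
   bent/plain distinction is a continuum in κ (preset B has κ = 0.67,
   preset A κ = 0.06) and no sharper invariant separates them.
5. **RC_ARC** otherwise.

## Time domain

Integration uses adaptive RK45, switching to Radau with the analytic
Jacobian for ε < 0.05 where the fast voltage jumps make the system
stiff.  Default tolerances rtol = 10⁻⁸, atol = 10⁻¹⁰; halving them
changes a reported limit-cycle period by < 0.1 % (tested).  Dense output
is resampled to ≥ 2000 points, scaled up to ≥ 64 samples (128 when
stiff) per characteristic period 2π/√|det J| so peaks are resolved;
every detected extremum is then polished on the solver's dense-output
polynomial, giving period estimates beyond grid resolution.

The perturbation protocol displaces the fixed point nearest u = 0 by
Δu (default ±1 V) at stationary w.  The default horizon is
200·max(τ_k, τ_m): for ε > 1 the roles of the time scales swap and τ_m
governs the slow decay, so scaling with τ_k alone would truncate the
transient of the fast-recovery presets.  Oscillation metrics discard the
first half of the record, then classify: sustained (≥ 5 late peaks with
period and amplitude CV < 1 %), damped (≥ 3 peaks of monotonically
shrinking amplitude; ring frequency from mean peak spacing), jump-to-sink
(terminal fixed point differs from the initial-adjacent one), monotonic
decay, else an explicit inconclusive error suggesting a longer horizon.

## Cross-validation and known limitations

Three independent routes are tied together by tests: the admittance
zeros equal the Jacobian eigenvalues (10⁻⁹ relative, 1000 random draws);
1/R_dc equals the finite-difference slope of I(u) and shares the sign of
det J; and the ring-down frequency of a 0.01 V perturbation at a stable
spiral matches |Im λ| within 1 % (decay rate within 5 %).

Two empirical caveats, established numerically with this package:

* **The Hopf onset is hysteretic.**  For preset C the bifurcation is
  subcritical: the large limit cycle (peak-to-peak ≈ 2.8 V) coexists
  with the stable focus in a window reaching ≈ 0.02 V above u_H, and its
  amplitude does not shrink as the bias approaches u_H from inside.  For
  preset D the supercritical branch canard-explodes within < 10⁻³ V of
  u_H.  Consequently (i) "spiking iff |u*| < u_H" is exact from inside
  but needs a guard band (0.05 V in the tests) on the stable side under
  large perturbations, and (ii) the frequency of the *observed* cycle
  near onset (C: 38 rad/s, D: 2.6 rad/s) is well below the linear
  eigenfrequency √(det J) (C: 53 rad/s, D: 11 rad/s), which describes
  only the infinitesimal — here non-attracting — cycle.
* Sub/supercritical character is observed in the time domain; no
  normal-form coefficients are computed, and no limit-cycle continuation
  is performed.

No stochastic forcing, multi-neuron coupling, or rescaling to the
classic dimensionless form is provided; impedance is forward-modelled
only (no fitting of measured spectra).
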