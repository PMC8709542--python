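# fhncircuit

Frequency- and time-domain analysis of the FitzHugh–Nagumo (FHN) neuron
model, written for computational neuroscientists and neuromorphic-device
engineers who want to read a neuron's dynamical regime straight off its
small-signal impedance spectrum.

The package treats the two-variable FHN model in electrical units,

```
C_m du/dt = I − (1/R_I)(u³/(3u₁²) − u) − w ,      C_m = τ_m/R_I
τ_k dw/dt = u/R_w − b w
```

and maps its linearization at a bias voltage onto an equivalent circuit:
membrane capacitor C_m, a bias-dependent channel resistance that is
*negative* inside the window |u| < u₁ (the built-in firing mechanism),
and a recovery branch R_a = bR_w in series with a chemical inductor
L = τ_k R_w.  From that one object it computes, cross-validated against
direct simulation:

- stationary I–u curves, nullclines and fixed points (closed-form cubic);
- trace/determinant stability classification and the analytic Hopf
  (u_H = u₁√(1−εb)), saddle-node (u_SN = u₁√(1−r/b)) and pitchfork
  (r = b) bifurcations, where ε = τ_m/τ_k and r = R_I/R_w;
- impedance spectra Z(iω) = 1/(iωC_m + G_b + 1/(R_a+iωL)) with automatic
  classification into five regimes (RC arc, bent arc, inductive loop,
  hidden NDR, negative R_dc) — the zeros of the admittance are exactly
  the Jacobian eigenvalues, so a purely imaginary impedance pole at
  ω = √(det J) *is* the Hopf bifurcation (Nyquist criterion);
- stiff-capable time-domain simulation with limit-cycle / ring-down /
  bistable-jump detection and phase-portrait assembly.

Presets `A`–`F` and `fig1a`/`fig1c` cover the standard illustration
parameter sets (R_I = 0.5 Ω, τ_m = 10⁻² s).

## Worked example

Where is the Hopf bifurcation of the r = 1 illustration set, and what
does the neuron do on either side of it?

```sh
$ fhncircuit repro fig1c
u_H = +-0.95917 V
I_H = +-1.06787 A
```

The fixed point is unstable — and the neuron spikes — for |u*| < 0.959 V,
i.e. drive currents |I| < 1.068 A.  The same machinery over the preset
table:

```sh
$ fhncircuit repro table1
model   b   r  epsilon  u_Hopf
    A 1.0 1.2   20.000
    B 1.0 1.2    1.800
    C 1.0 1.2    0.316 0.82704
    D 1.0 1.2    0.010 0.99499
    E 1.2 0.8    0.010 0.99398
    F 1.1 0.8    0.010 0.99448
```

Models A and B (εb > 1) have no Hopf bifurcation and never spike.  The
impedance spectrum announces the spiking regime without any time-domain
run — model C biased inside its Hopf window:

```sh
$ fhncircuit classify --model C --u 0.5
regime = HIDDEN_NDR
Re Z sign change at omega = 24.4773 rad/s
real-axis crossing at omega = 52.853 rad/s
bend ratio kappa = L/(R_a^2 C_m) = 3.797
```

Re Z turns negative at finite frequency while R_dc stays positive: the
"hidden" negative differential resistance that marks a limit cycle
around an unstable focus.  On the stable side of the Hopf the response
is a decaying spiral whose frequency the linearization predicts:

```sh
$ fhncircuit perturb --model C --u-bias 0.9 --du 1 --t-end 1.5
kind = damped_oscillation
terminal_u = 0.900051
ring_frequency = 56.1313
```

(|Im λ| = 56.14 s⁻¹ at this bias — the ring-down frequency agrees to
0.02 %.)  Equivalent library calls: `fhncircuit.bifurcation_summary`,
`fhncircuit.classify_spectrum_detail`, `fhncircuit.perturbation_response`
+ `oscillation_metrics`; see `docs/methods.md` for the model and the
numerical choices.

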