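# Methods

## Models

**Ball-and-stick (BS).** A lumped somatic compartment (capacitance C_s,
leak G_s, optional exponential spike-initiation current with slope Δ_T and
threshold V_T) attached at x = 0 to a finite passive cable of length L
(per-length constants c_m, g_m, axial g_i), sealed at x = L. All voltages are
deviations from rest; the resting potential itself never appears. Synaptic
currents enter at the soma (I_s) and as a flux at the distal end (I_d). A
spatially uniform extracellular field E(t) enters only through the two
boundary conditions, with opposite signs — the standard description of a
uniform-gradient extracellular potential along a straight cable in a purely
ohmic medium. Spikes: when the somatic voltage reaches the cutoff V_s from
below, the time is recorded, the soma is reset to V_r and held there
(Dirichlet clamp) for the refractory period T_ref while the cable keeps
evolving, then the somatic boundary condition resumes. The clamp actively
sinks axial current during the refractory window; how the dendrite should be
treated during the clamp is not uniquely determined by the model statement,
and this choice (the most literal reading of "V(0,t) is clamped at V_r") is
one of the package's fixed conventions.

**Extended point (eP).** A single-compartment integrate-and-fire membrane
with C = C_s, G = G_s whose drive is the sum of the somatically filtered
input [L_s ∗ I_s], the distally filtered input [L_d ∗ I_d], and the
field-equivalent current I_E(t) = |B(φ)| sin(φt + arg B(φ)). The filters and
B are exact consequences of the linear subthreshold cable solution, so for
the LIF membrane the eP somatic voltage equals the BS somatic voltage
identically in the subthreshold regime; for the EIF membrane the somatic
exponential term is linearized around a baseline V_0 (default V_r) in the
derivation, and the eP carries the full exponential term scaled by
α = G_s/(G_s + tanh(L/λ) g_i/λ), λ = √(g_i/g_m), which makes the
quasi-static current–voltage relations (and hence all DC fixed points) of
the two models coincide exactly. Point models reset to the elevated
V_r' = (V_r + V_T)/2 to mimic the residual dendritic depolarization after a
BS spike.

**P model.** The same point membrane without the extension (identity
filters, α = 1), calibrated per input condition: G_P is the reciprocal of
the BS DC impedance at the input site (somatic: X(0); distal:
X(0)/sech(L/λ), both in their Δ_T → 0 form), and C_P maximizes the
coincidence factor Γ against a 52 s BS reference train sharing the same
input realization — a 17-point log-spaced scan of C_P over [0.2, 5]·C_s
followed by golden-section refinement of the bracketing interval to 1%
relative width. The search grid and the calibration train length are package
conventions; only the two matching objectives are inherent to the method.

## Parameters and defaults

All internal physics is SI; the trace/spike-train layer and the CLI use
mV / pA / ms. Defaults (the starred parameter set):

| parameter | default | meaning |
|---|---|---|
| c | 1e-2 F/m² | specific membrane capacitance |
| ρ_m | 1/2.8 S/m² | specific membrane conductance (τ_m = c/ρ_m = 28 ms) |
| ρ_i | 1/1.5 S/m | specific internal (axial) conductance |
| D_s | 10 µm (5–15) | soma diameter → C_s = c·D_s²π, G_s = ρ_m·D_s²π |
| D_d | 1.2 µm (0.6–1.8) | cable diameter → c_m, g_m, g_i |
| L | 700 µm (350–1050) | cable length; λ = √(g_i/g_m) ≈ 748 µm |
| V_T, Δ_T | 10 mV, 1.5 mV | exponential-term threshold and slope (Δ_T = 0 ⇒ LIF) |
| V_r, V_r′, V_s | 0, 5, 20 mV | resets and cutoff (V_s = V_T in the LIF limit) |
| T_ref | 1.5 ms | refractory period |
| V_0 | V_r | EIF linearization baseline (a parameter, not a constant) |
| τ | 0.5 ms | OU input correlation time |
| Δ | 3 ms | spike-coincidence precision |
| E1 | 1 or 10 V/m | field amplitude; field frequency 0–10 kHz |

## Synthetic inputs

Synaptic drive is an Ornstein–Uhlenbeck current with mean I_x0, stationary
standard deviation σ_x and correlation time τ = 0.5 ms, generated with the
exact update I_{n+1} = I_0 + (I_n − I_0)e^{−dt/τ} + σ√(1 − e^{−2dt/τ}) η_n
and a stationary initial draw. Since τ is comparable to the integration step,
an Euler–Maruyama generator would distort the stationary variance; the exact
update is distributionally correct at any dt (verified by a two-sample KS
test between dt and dt/2 traces). One master seed spawns independent
substreams per trial and input site, so a BS/eP comparison shares a
bit-identical realization while trials remain independent. The field is
E(t) = E1 sin(2πf t).

What the generator emulates: stationary, Gaussian, exponentially correlated
in-vivo-like input current. What it does not: conductance-based synapses
(no reversal-potential coupling between input and voltage), shot noise,
nonstationary rates. Conclusions drawn from passing tests therefore concern
the models under stationary current-based drive only.

## Numerics

**Cable solver.** Node-centered grid with the soma at node 0, default 50
cable segments. Both Robin boundary conditions are folded in by ghost-node
elimination, which attaches half a segment of cable membrane to each boundary
row and keeps the spatial scheme second order (first-order one-sided
differences visibly bias the field response at 50 segments). Time stepping is
a θ-scheme over the linear part with the somatic exponential term evaluated
explicitly at the previous step, so every step is one constant-coefficient
tridiagonal (Thomas) solve inside a numba kernel. θ = 1 (backward Euler) is
the default for all spike-train work: it is L-stable and robust to the reset
discontinuities. θ = 0.5 (trapezoidal) is used for subthreshold accuracy
studies: backward Euler's O(dt) phase error is amplified exponentially
through the cable attenuation sech(z(ω)L) at high drive frequency (≈30%
response error for distal 1 kHz drive at dt = 25 µs), whereas the
trapezoidal rule meets a 2% amplitude-and-phase tolerance at
(100 segments, dt = 25 µs) for all drives up to 1 kHz — the tolerance used
by every solver-vs-closed-form comparison. Default steps: dt = 0.05 ms
(LIF), 0.025 ms (EIF). Blow-up (a non-finite somatic voltage, possible only
with the exponential term) raises an error naming the step; finite
excursions above V_s are legitimate overshoot and are simply reset.

**Point solver.** Forward Euler at the same step as the BS run, numba-jitted;
spike at V ≥ V_s, reset to V_r', clamp for T_ref.

**Filters.** Applied spectrally: FFT of the input trace, multiplication by
the filter at the transform's frequency grid (the filters' sgn(ω) branch
makes them Hermitian, so negative frequencies need no special casing),
inverse FFT. The trace is treated as periodic; one membrane time constant
(28 ms) of mirrored samples is prepended/appended and trimmed afterwards to
suppress wrap-around transients. The Nyquist bin is forced real. Realness of
the output is asserted (imaginary residue < 1e-10 of the signal scale), not
assumed. The Fourier convention multiplies the e^{+iωt} component by the
transfer value, which yields the physically correct lag for a passive
membrane; the closed forms are used unchanged on numpy's FFT grid because
numpy's inverse transform reconstructs exactly that component.

**Degenerate inputs and conventions.** Δ_T = 0 means "omit the exponential
term", never a division. z, tanh(zL) and sech(zL) are computed from scaled
exponentials (|zL| ≫ 1 at 10 kHz and L = 1050 µm would overflow cosh).
Spike times are the first sample at or above V_s — no sub-step
interpolation; the 3 ms coincidence precision makes sub-dt timing
immaterial. Γ coincidences are counted by greedy earliest-first one-to-one
matching (equal to maximum matching for tolerance-window graphs, and
reproducible); Γ is returned as NaN, flagged undefined, when the comparison
rate approaches 1/(2Δ) and the normalization vanishes. The phase-histogram
rate normalization divides each bin's count by (total complete-cycle
time)/n_bins, which makes r0 the mean rate in Hz; r0 is fixed to the
histogram mean and (r1, ψ) come from a linear least-squares fit on the two
quadratures, with r1 ≥ 0 by construction and fits flagged when r1 > r0
(the sinusoidal rate description breaks down there).

## Scales used by the tests and the acceptance script

Spike-train comparisons run 3 independent realizations of 50 s each
(calibration trains 52 s), Δ = 3 ms. Modulation sweeps use 100 trials of
12 s with the first 2 s discarded and complete field cycles only, eP model
only — the package's standard desk scale; trial counts and durations are
configuration fields, not constants. Subthreshold oracle comparisons discard
a 300 ms startup window, because the BS and eP models approach the driven
solution from rest with different relaxation times (≈C_s/X(0) vs
C_s/G_s = 28 ms); the steady-state identity is the claim being tested.

## Known limitations

* **EIF spike-train reproduction.** With the α-scaled exponential term, the
  eP model's quasi-static fixed points match the BS model exactly, but its
  spike upswing from the unstable point to the cutoff V_s is roughly
  G_s/X(0) ≈ 7× slower than the BS soma's (full exponential current, cable
  drained): many noise-initiated upswings stall or lag beyond the 3 ms
  coincidence window. At the moderate somatic input (mean 5.05 pA,
  σ 24.08 pA) the eP fires at ≈55% of the BS rate and Γ_BS,eP ≈ 0.45,
  converged in dt. Both simulators were cross-validated against an
  independent stiff-ODE integration of the same equations, so this is a
  property of the model equations as implemented here, not of the numerics.
  The LIF extension does not share this limitation (Γ ≈ 0.92 at the weak
  somatic input).
* **|B| monotonicity.** The field-equivalent current magnitude grows with
  frequency up to 10 kHz for the default morphology, but for a short, thin
  cable with a large soma (350 µm, 0.6 µm, 15 µm) it has a shallow (≤4%)
  shoulder near a few hundred hertz where the sensitivity falls faster than
  the membrane admittance grows.
* Passive dendrite only; one unbranched cable; current-based synapses;
  uniform field. Broadband (non-sinusoidal) fields are supported in
  principle by per-frequency multiplication with B(φ)/E1, but only the
  sinusoidal path is exercised by tests.
* The refractory Dirichlet clamp sinks axial charge; alternative clamp
  conventions would change post-spike recovery slightly at high rates.
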