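# dendrifield

Simulation and analysis tools for studying how a neuron's dendrite shapes its
response to synaptic input and to weak, oscillatory extracellular electric
fields — the kind of field produced by transcranial electrical stimulation or
by endogenous population activity.

Point (single-compartment) integrate-and-fire neurons are the workhorse of
large-scale network modeling, but they have no spatial extent, so a spatially
uniform field cannot polarize them at all, and they miss the frequency-dependent
filtering a dendrite imposes on synaptic input. `dendrifield` implements both
sides of the remedy:

* a **ball-and-stick (BS) reference model** — a lumped leaky/exponential
  integrate-and-fire soma attached to a finite passive cable — solved by
  finite differences, with synaptic input at the soma and/or the distal
  dendritic end and a uniform field entering through the cable boundary
  conditions; and
* an **extended point (eP) model** that reproduces the BS somatic voltage with
  analytically derived components: two linear input filters, a
  field-equivalent current, and (for the exponential membrane) a scaling
  factor for the spike-initiation current.

## The model in brief

The cable voltage deviation V(x, t) obeys

```
c_m ∂V/∂t − g_i ∂²V/∂x² + g_m V = 0,              0 < x < L,
C_s ∂V/∂t − g_i ∂V/∂x + G_s V − G_s Δ_T e^{(V−V_T)/Δ_T} = I_s(t) − g_i E(t),   x = 0,
∂V/∂x = I_d(t)/g_i + E(t),                         x = L,
```

with an integrate-and-fire reset at the soma (spike when V(0,t) ≥ V_s, reset
to V_r, refractory clamp for T_ref). Solving the subthreshold system in the
frequency domain gives every somatic response component over a common
denominator

```
X(ω) = C_s iω + G_s(1 − e^{(V_0−V_T)/Δ_T}) + z(ω) g_i tanh(z(ω)L),
z(ω) = √((g_m + √(g_m² + ω²c_m²))/(2g_i)) + sgn(ω) i √((−g_m + √(g_m² + ω²c_m²))/(2g_i)),
```

from which the package derives, in closed form: the somatic and distal input
impedances 1/X and sech(zL)/X, the eP input filters
L̂_s = (C_eP iω + G_eP(1 − α e^{(V_0−V_T)/Δ_T}))/X (high-pass) and
L̂_d = L̂_s · sech(zL) (low-pass), the field response
A(φ) = E1 g_i [sech(zL) − 1]/X (a polarization length |A|/E1 of ≈ 0.3 mm at
low frequency for the default morphology), the field-equivalent current
B(φ) = A(φ) · (C_eP iφ + G_eP(1 − α e^{(V_0−V_T)/Δ_T})), and
α = G_s/(G_s + tanh(L/λ) g_i/λ) with λ = √(g_i/g_m).

The eP membrane is then simulated as
`C dV/dt + G V − α G Δ_T e^{(V−V_T)/Δ_T} = [L_s∗I_s] + [L_d∗I_d] + I_E`,
with filters applied spectrally to the same Ornstein–Uhlenbeck input
realizations that drive the BS model, so the two spike trains can be compared
spike for spike with the coincidence factor Γ, and field-locked spike-rate
modulation r(t) = r0 + r1 sin(φt + ψ) can be estimated across field
frequencies.

## Worked example

Drive the BS model and the eP model with the *same* noisy somatic current and
compare their spike trains:

```python
from dendrifield import (BiophysicalParams, SpikeMechanismParams, lif_limit,
                         OUParams, ou_trace, simulate_bs, simulate_ep,
                         coincidence_factor)

bio = BiophysicalParams()                      # 10 um soma, 700 um x 1.2 um cable
lif = lif_limit(SpikeMechanismParams())        # leaky integrate-and-fire membrane

drive = ou_trace(OUParams(mean=4.68, sigma=11.94, seed=1), duration=20e3, dt=0.05)
bs = simulate_bs(bio, lif, I_s=drive)          # ball-and-stick reference
ep = simulate_ep(bio, lif, I_s=drive)          # extended point model, same input

gamma = coincidence_factor(bs.spikes, ep.spikes, delta=3.0).gamma
print(f"BS rate: {bs.spikes.rate:.2f} Hz   eP rate: {ep.spikes.rate:.2f} Hz")
print(f"coincidence factor Gamma (Delta = 3 ms): {gamma:.3f}")
```

prints

```
BS rate: 6.30 Hz   eP rate: 6.00 Hz
coincidence factor Gamma (Delta = 3 ms): 0.923
```

i.e. over a 20 s train the extended point model reproduces more than 90% of
the spatial model's spikes to 3 ms precision without any fitted parameter
(Γ = 1 would be a perfect match, Γ = 0 chance level). The subthreshold field
sensitivity and its anti-phase relation to the field come straight from the
closed form:

```python
import numpy as np
from dendrifield import BiophysicalParams, derive_cable_params, transfer

cable = derive_cable_params(BiophysicalParams())
for f in (0.5, 10, 100, 1000):
    A = complex(transfer.field_response_A(2 * np.pi * f, 1.0, cable))
    print(f"f = {f:6.1f} Hz   sensitivity |A|/E1 = {abs(A)*1e3:.3f} mm"
          f"   phase = {np.angle(A):+.2f} rad")
```

```
f =    0.5 Hz   sensitivity |A|/E1 = 0.283 mm   phase = +3.13 rad
f =   10.0 Hz   sensitivity |A|/E1 = 0.279 mm   phase = +2.98 rad
f =  100.0 Hz   sensitivity |A|/E1 = 0.144 mm   phase = +2.20 rad
f = 1000.0 Hz   sensitivity |A|/E1 = 0.025 mm   phase = +1.89 rad
```

A 1 V/m field polarizes the soma by ~0.28 mV at low frequency (phase ≈ π:
the soma is hyperpolarized at the field peak), and the sensitivity falls with
frequency while the field-equivalent current |B| grows.

A thin CLI wraps the experiment drivers:

```sh
dendrifield sensitivity                 # tabulate |A|/E1 and |B| vs frequency
dendrifield filters --model eif         # tabulate the input filters
dendrifield run my_experiment.yaml      # config-driven Gamma grids / resonance sweeps
```

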