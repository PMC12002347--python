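# pharynxsim

Conductance-based simulation and analysis of plateau potentials in the
*C. elegans* pharyngeal corpus muscle, centered on the unusual
ultrafast-inactivating K⁺ conductance (EXP-2) that terminates them.

The pharynx feeds the worm by rhythmic pumping driven by myogenic plateau
potentials: ~250 ms depolarizations to ≈ +40 mV, initiated by excitatory
MC input and terminated by inhibitory M3 input.  EXP-2 inverts the usual
delayed-rectifier logic — it *inactivates* almost instantly on
depolarization and sits primed (activation w saturated, inactivation h
closed) until a hyperpolarizing input deinactivates it, whereupon it
repolarizes the muscle.  Because synaptic signaling in these tiny,
high-impedance cells is noisy, the question is quantitative: how large a
hyperpolarizing fluctuation terminates a plateau early, and how does that
depend on the half-inactivation voltage V½ and the inactivation time
constant τh?

The package is aimed at computational neurophysiologists who want to
rerun, extend or stress-test that analysis.

## The model

A single isopotential compartment:

```
C dV/dt = −gL(V−VL) − gCaT mT²hT(V−VCa) − gK w h (V−VK)
          − gCaL mL²hL(V−VCa) − gE(V−VsynE) − gI(V−VsynI)
```

with a T-type (CCA-1-like) trigger current, an L-type (EGL-19-like)
plateau current, the EXP-2-like IK (h = h∞(V) in the ultrafast variant,
first-order with τh otherwise, `h∞ = 0.5(1 − tanh((V−V½)/k))`), and
event-driven exponential synapses.  Commands assign gE/gI their maximal
values; Poisson shot noise adds 0.15 nS quanta to the inhibitory
conductance.  Units: mV, ms, nS, pF, pA throughout.  See
`docs/methods.md` for every gating curve, the reconstructed constants and
their calibration, numerical choices, and known limitations.

## Worked example

```python
from pharynxsim import (ModelParameters, NoiseConfig,
                        simulate_reference_protocol, detect_plateaus)
from pharynxsim.plateaus import closed_durations

for lam in (0.0, 0.01, 0.05):
    p = ModelParameters(Vhalf_inact=20.0)           # depolarized midpoint
    tr = simulate_reference_protocol(p, NoiseConfig(lam=lam, seed=1),
                                     t_total=60_000.0, seed=1)
    d = closed_durations(detect_plateaus(tr))
    print(f"lam={lam}: {d.size} plateaus, mean {d.mean():.1f} ms")
```

prints

```
lam=0.0: 120 plateaus, mean 249.4 ms
lam=0.01: 120 plateaus, mean 115.5 ms
lam=0.05: 120 plateaus, mean 41.4 ms
```

Noiselessly, every commanded plateau runs its full 250 ms.  With the
half-inactivation voltage shifted to +20 mV, the deinactivation zone of
IK sits close under the plateau, and even low-rate inhibitory shot noise
(λ = 0.01) cuts the mean duration below half the commanded length; at
high noise (λ = 0.05) plateaus barely outlive their first tens of
milliseconds.  Repeating this with `Vhalf_inact=10.0` leaves the mean
within one millisecond of 249.4 — the hyperpolarized midpoint hides the
deinactivation zone beyond the reach of noise fluctuations.

The same objects drive the full studies:
`run_conductance_sweep` (regime map over gK × gCaL:
low-amplitude → physiological → unending, plus two-level cells of the
slow-τh variants), `run_noise_robustness` (V½ ∈ {10, 15, 20} × λ ∈
{0, 0.01, 0.05} with Mann–Whitney effect sizes r = |z|/√N against the
noiseless condition), `run_timescale_robustness` (τh ∈ {1, 5, 10, 20} ms)
and `run_timescale_interaction` (τh × synaptic-τ interaction curves).

A CLI mirrors them: `pharynxsim simulate|sweep|noise|timescales|
interaction|stats`, each writing tidy CSVs plus a JSON manifest
(resolved config + seeds) from which any run can be reproduced exactly.

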