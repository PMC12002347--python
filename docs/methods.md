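# Methods

## The model

The pharyngeal corpus muscle of *C. elegans* is represented as a single
isopotential compartment obeying a Hodgkin–Huxley-type current balance

```
C dV/dt = −gL (V − VL)
          − gCaT mT² hT (V − VCa)
          − gK  w  h    (V − VK)
          − gCaL mL² hL (V − VCa)
          − gE (V − VsynE) − gI (V − VsynI)
```

with V in mV, t in ms, conductances in nS and C in pF, so currents are in
pA and no unit conversion factors appear.

The four intrinsic currents are:

* **leak** (gL = 2 nS, VL = −65 mV);
* **ICaT**, a T-type (CCA-1-like) calcium current that converts the brief
  excitatory synaptic input into a regenerative depolarization.  Its
  activation mT is fast (sub-millisecond to a few ms) with midpoint
  −45 mV; its inactivation hT (midpoint −40 mV, slope 3 mV) shuts the
  current off within a few ms of depolarization and recovers at rest with
  τ ≈ 63 ms;
* **ICaL**, an L-type (EGL-19-like) calcium current that carries the
  plateau.  mL activates steeply above −20 mV with a sub-millisecond time
  constant at depolarized potentials.  hL inactivates only partially
  (steady state ≈ 0.85 at plateau voltages) and slowly (τ ≈ 200–300 ms),
  which produces the slow sag of the plateau from its initial peak near
  +41 mV toward +38 mV;
* **IK**, the EXP-2-like potassium current, the object of the study.  Its
  activation w follows `dw/dt = 0.04 (w∞ − w)/τw` with w∞ a tanh sigmoid
  (midpoint +12 mV, slope 17.4 mV) and τw ≤ 1 ms; the 0.04 rate
  multiplier makes the effective activation time ~5 ms at rest and
  ~20 ms at the plateau, so w saturates during a plateau and deactivates
  between plateaus.  Its inactivation gate h has steady state
  `h∞ = 0.5 (1 − tanh((V − V½)/k))`.  In the **ultrafast** variant h
  tracks h∞(V) instantaneously; in the **finite-τh** variants
  `dh/dt = (h∞ − h)/τh` with τh ∈ {1, 5, 10, 20} ms.

At the plateau (≈ +40 mV) w is saturated (> 0.95) while h∞ is effectively
zero: the channel is *primed but non-conducting*.  A sufficiently large
hyperpolarizing excursion deinactivates the channel, which then carries a
large outward current and repolarizes the cell — the plateau-termination
mechanism whose noise sensitivity the experiments quantify.

Synaptic drive is event-based: a presynaptic spike *assigns* the maximal
conductance (gE := 3 nS for the excitatory MC input, gI := 2.5 nS for the
inhibitory M3 input), which then decays exponentially (τE = 1 ms,
τI = 2 ms).  Shot-noise events *add* quanta of 0.15 nS to gI (addition
rather than assignment, so a noise quantum cannot erase a commanded
IPSP).  Noise is inhibitory-only: during a plateau the muscle sits far
above the reversal of mixed-cation channels, so stochastic channel
openings hyperpolarize.

## Reconstructed and calibrated constants

Several constants of the published model could not be taken at face
value, either because the printed equations are typographically corrupted
or because a value is not stated at all.  This package fixes them by
requiring the model to reproduce the qualitative and quantitative
behavior the study reports, in this order of authority: (1) plateau
morphology (commanded 250 ms plateaus near +40 mV, resting near −65 mV),
(2) the noiseless identity of the three V½ variants, (3) the reported
noise-collapse pattern.  The calibration was done once, before the test
suite was frozen.

* **Gating-curve algebra.**  Where printed fractions collapsed
  typographically, the reciprocal readings were adopted: τw = 1/cosh((V −
  12)/34.8), τmT = 1/(0.5 cosh((V − 14.5)/34.8)), τhT = 65/(1 +
  exp((V + 40)/7)), τmL = 1/(1 + exp((V + 27)/10)).  The printed
  steady-state/time-constant pair for hL cannot be correct as labelled (a
  steady state must lie in [0, 1]); the labels are swapped so that
  hL∞ = 1/(1 + exp((V − 135)/55)) and τhL = 200 + 100/(1 +
  exp((V + 40)/7)) ms, giving partial, slow L-type inactivation.
* **Membrane capacitance** is never stated.  It must be small enough that
  the 1-ms EPSP can drive the membrane into the Ca-activation range
  before the synapse decays: at C = 10 pF (membrane τ = 5 ms) no plateau
  is ever triggered; any C ≲ 5 pF works and the plateau morphology is
  essentially C-independent below that.  Default: **C = 2 pF**.
* **K-inactivation slope k.**  The printed h∞ expression is mangled
  beyond recovery; the sign convention (midpoint at +V½) is forced by the
  reported robustness ordering (V½ = 10 most robust, 20 least).  The
  slope is then pinned by the collapse quantities: the plateau sits at
  +38–41 mV and a single 0.15-nS quantum produces a 2–3 mV dip (a
  quasi-static bound independent of C), so with a 3-mV slope the
  deinactivation zone for V½ = 20 starts ~14 mV below the plateau and no
  noise collapse can occur at all, while slopes ≥ 7.5 destabilize the
  noiseless V½ = 20 plateau.  Default: **k = 7 mV**, the value at which
  all three V½ variants are noiseless-stable at 250 ms and the reported
  collapse pattern appears.
* **Poisson interval.**  The shot-noise rate λ is defined per sampling
  interval, which is not stated.  With 1-ms bins, events are isolated
  single quanta and cannot stack within the 2-ms synaptic decay, which
  again forbids the reported low-noise collapse; with 0.1-ms bins the
  compound-dip distribution is graded and the full pattern (collapse at
  V½ = 20 under λ = 0.01 and 0.05, partial suppression at V½ = 15 under
  high noise only, immunity at V½ = 10) emerges.  Default:
  **bin = 0.1 ms**, i.e. mean event rates of 0.1/ms (λ = 0.01, "low")
  and 0.5/ms (λ = 0.05, "high").

With these constants frozen, the noiseless model produces 250-ms
commanded plateaus for every V½ (mean 249.4–250.0 ms), and under noise
the pooled mean duration falls to ≈ 115 ms (V½ = 20, λ = 0.01),
≈ 40 ms (V½ = 20, λ = 0.05) and ≈ 180 ms (V½ = 15, λ = 0.05) while
V½ = 10 stays within 1 ms of the noiseless value.

## Stimulus generation

`build_feeding_schedule` produces the deterministic command list: EPSPs
at `t_first + k·(plateau + isi)` and IPSPs `plateau` later, with the
reference timing 250/250 ms and a 100-ms warm-up after resting-state
initialization.  `sample_noise_train` draws an independent Poisson(λ)
count per bin and emits one event per nonzero bin at the bin start with
magnitude `count × 0.15 nS`.  Identical (seed, λ, bin, duration) give a
byte-identical train; simultaneous events are ordered EPSP < IPSP <
NOISE.  What the generator deliberately does not emulate: excitatory
noise, synaptic depression/facilitation, presynaptic membrane dynamics,
and any correlation structure between events — so tests passing under
this noise model say nothing about temporally correlated or
state-dependent noise in real pharynxes.

## Numerics

The vector field is smooth between synaptic events, and every event is a
known conductance discontinuity, so integration restarts at each event
(the jump is treated exactly) using LSODA (adaptive, stiffness-switching;
τmL drops below 2 µs at plateau voltages, so a stiff method is
mandatory).  Tolerances default to rtol 1e-6 / atol 1e-9; halving them
changes the reference trace by ≈ 1e-4 mV.  Output is sampled on a uniform
0.5-ms grid; samples falling exactly on an event time record the
pre-event (left-limit) state.  Long runs are integrated in chunks
(default 50 s) with the plateau detector operating as a streaming
accumulator across chunk boundaries; chunked and single-call results
agree to the solver-convergence scale.  The resting state is found by
scanning the steady-state ionic current on [−80, 0] mV for stable roots,
followed by a 500-ms relaxation polish.

The compiled (numba) kernel duplicates the gating algebra of the public
reference implementation; a test compares the two on random states to
1e-12.

## Plateau measurement

Plateaus are maximal intervals with V ≥ −30 mV (midway between rest and
plateau) lasting ≥ 5 ms, with crossing times interpolated linearly
between samples.  Segments still above threshold at the end of a trace
are flagged open-ended and excluded from duration statistics; an
open-ended segment spanning ≥ 2 stimulus periods marks the *unending*
regime.  A termination within 25 ms after a scheduled IPSP counts as
commanded.  Two-level plateaus are detected from the dwell-time histogram
of V within a segment (2-mV bins): two local dwell maxima ≥ 50 ms each,
≥ 20 mV apart, with the upper band occupied before the lower one.  The
regime classifier applies the precedence unending > two_level >
physiological > low_amplitude > quiescent.

The wedge (the transient hyperpolarization after plateau onset in slow-τh
variants) is scored as the dip between the initial peak and the
subsequent local minimum *from which V recovers*; a plateau that merely
relaxes monotonically scores zero.  In this reconstruction the wedge of
the τh = 10 ms variant does not rebound — it either stays shallow or, at
τh = 20 ms, proceeds directly to the lower level — so the monotone
wedge-deepening property is asserted on the early-plateau minimum
voltage, which decreases strictly in τh over {1, 5, 10, 20} ms.

## Statistics

Noisy and noiseless duration samples are compared with the two-tailed
Mann–Whitney U test (midranks, tie-corrected variance, no continuity
correction; the tie-corrected variance equals the exact permutation
variance, which the tests verify by enumeration).  The effect size is
r = |z|/√N with N the total number of plateaus in both samples.

Durations are quantized to 2 ms (< 1 % of the commanded plateau) before
the rank comparison.  Rationale: a rank test run on raw interpolated
durations registers *any* consistent shift, including the
sub-resolution (≲ 0.3 ms) timing shifts that every noise event imprints
on threshold crossings and the solver's own jitter, and with thousands of
plateaus this drives |z| to its maximum even when the biology is
unaffected.  The 2-ms resolution absorbs sub-resolution shifts while
leaving genuine truncations (tens to hundreds of ms) fully visible.
Means are always computed on raw durations.

## Experiment problem sizes

The packaged defaults follow the study design (1,000 s per condition;
41 × 31 sweep grid at 0.25 nS).  The test-suite and acceptance-script
runs use deliberately desk-scale sizes chosen so each condition still
contains hundreds of plateaus: 200 s × 3 seeds for the noise-collapse
quantities, 100 s × 3 seeds for the timescale comparisons, 50 s per cell
for the interaction curves, 3-s protocols per sweep cell.  Each stochastic
condition derives its noise seed from the base seed via
`SeedSequence([base, condition coordinates])`, so conditions are
independent and extending a study never reshuffles existing seeds.

The two-level search used by the acceptance script sweeps the
conductance plane coarsely (0.5 nS), then refines gCaL at 0.05 nS inside
each physiological→unending bracket, because the two-level band is
narrower than any practical coarse grid.

## Known limitations and divergences

* The constants C, k and the Poisson bin are reconstructions pinned by
  reported behavior, not published values; other (C, k, bin) triples in
  a narrow neighborhood would serve equally.
* Noiseless plateau durations are *not* bit-identical across V½: the
  inactivation midpoint necessarily enters the repolarization
  trajectory, so durations differ by ~0.5 ms (249.45 ms at V½ = 15/20
  vs 249.96 ms at V½ = 10).  The published "identical output" holds at
  figure resolution only.
* In this reconstruction the τh = 20 ms variant's two-level state is
  robust to shot noise (its lower level is strongly stabilized by the
  steep w∞ slope), so the reported pronounced noise effect for τh =
  20 ms does not reproduce; the biphasic ordering is carried by
  τh = 1/5 vs 10 ms.
* Two-level cells occur at gK ≈ 3.5–5.5 nS with upper/lower bands near
  +31/+7 mV rather than +40/0 mV; the bands' separation and temporal
  structure match the description, their absolute voltages sit ~5–8 mV
  low.
* The model omits Ca²⁺ dynamics, muscle mechanics, temperature
  dependence, stochastic channel gating, and the rest of the pharyngeal
  network.
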