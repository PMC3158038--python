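# Methods

`ssanet` simulates stimulus-specific adaptation (SSA) in small spiking
networks whose only adaptive element is short-term synaptic depression.
This note documents the model equations, the parameter choices and their
provenance, the numerical scheme, the statistical design of the shipped
test batteries, and the limitations of each.

## Model

### Input population (A)

Population A consists of sub-populations of independent Poisson units.
Sub-population best frequencies are spaced uniformly on an octave axis
centred on zero: 96 sub-populations over 2 octaves for two-tone tasks,
144 over 3 octaves for multi-tone tasks.  The firing rate of a
sub-population with best frequency `phi` in response to a tone at
frequency `f` follows a raised Gaussian,

    r(f) = r_spont + (r_max - r_spont) * exp(-(f - phi)^2 / (2 sigma^2)),

with `sigma = b / (2 sqrt(2 ln 2))` so that the *bandwidth* `b` is
exactly the octave separation between the two frequencies that evoke the
rate halfway between `r_max` and `r_spont`.  Defaults: `r_max` = 100 Hz,
`b` = 0.5 octaves, `r_spont` = 0.5 Hz.

The low input spontaneous rate is a deliberate choice.  The A→B synapses
recover slowly (800 ms); with 63 % of the transmitter resource consumed
per presynaptic spike, an input channel firing spontaneously at `nu` Hz
sits at a steady-state recovered fraction of roughly
`1 / (1 + 0.63 * nu * 0.8 s)`.  At 5 Hz this is ~0.3 — chronic,
frequency-unspecific depression that erases the stimulus specificity the
model exists to produce.  At 0.5 Hz the resting resource is ~0.8.  The
high spontaneous *output* activity that makes the model's SSA indices
conservative is instead supplied by the conductance noise injected into
every integrate-and-fire unit (below), which bombards the membrane
without touching the feed-forward synapses.

### Neurons (B, C, D)

All non-Poisson units are adaptive exponential integrate-and-fire (AdEx)
neurons,

    C dV/dt     = -g_L (V - E_L) + g_L Delta_T exp((V - V_T)/Delta_T) - w + I
    tau_w dw/dt = a (V - E_L) - w,

with a spike registered when `V` crosses a 0 mV detection cutoff, after
which `V → V_reset` and `w → w + b`.  Parameters are the regular-spiking
set of the model's source description (C = 281 pF, g_L = 30 nS,
E_L = V_reset = −70.6 mV, Delta_T = 2 mV, V_T = −50.4 mV,
tau_w = 144 ms, a = 4 nS, b = 80.5 pA), stored in `defaults.yaml`.

### Background noise

Every AdEx unit receives an in-vivo-like fluctuating conductance input:
two independent Ornstein–Uhlenbeck conductances (excitatory and
inhibitory) with the point-conductance parameters
g_e0 = 12.1 nS, g_i0 = 57.3 nS, tau_e = 2.73 ms, tau_i = 10.49 ms,
sigma_i = 6.6 nS, E_e = 0 mV, E_i = −75 mV.  The conductances are not
clipped at zero (the underlying OU process admits negative excursions);
clipping is available as an opt-in.  A single multiplicative
`area_scale` factor (default 1.0) stands in for membrane-area
compensation.

Two presets differ only in the excitatory sigma:

* `high_spontaneous` (AB and ABC models): sigma_e = 23.4375 nS, tuned
  with `ssanet.neurons.calibrate_noise_sigma` (bisection on the measured
  spontaneous rate of an isolated unit) to ~5 Hz spontaneous firing,
  representative of high spontaneous activity in auditory cortex.
* `low_spontaneous` (ABD model): sigma_e = 3.0 nS, the original
  point-conductance value — membrane fluctuations but almost no
  spontaneous spikes.

### Synapses

All synapses share one three-state transmitter-resource scheme.  A unit
supply of resource is split between recovered (R), effective (E) and
inactive (I) fractions, R + E + I = 1.  A presynaptic spike opens (or
re-opens, without stacking) a square transmitter pulse of duration 1 ms;
while the pulse is open, R converts to E at rate R/tau_rise; E
inactivates at E/tau_decay; I returns to R at I/tau_rec.  The
postsynaptic current is `I_syn = w * E * (E_rev - V)`.

Three classes:

* fast excitatory, non-depressing (A→C): kinetic AMPA-like constants
  (tau_rise = 1 ms, tau_decay = 5.26 ms), E_rev = 0 mV, with an
  *instantaneous* I→R return — realized by transferring the whole
  inactive fraction back to recovered each step, so the depressing and
  non-depressing classes share one code path and the non-depressing
  synapse is exactly the tau_rec → 0 limit;
* fast inhibitory (C→B): the same scheme with GABA_A-like decay
  (5.6 ms) and E_rev = −75 mV; shunting behaviour arises from the
  driving force alone;
* fast excitatory with rapid depression and slow recovery (A→B, B→D):
  the AMPA-like kinetics plus a slow recovery constant
  tau_rec = 800 ms, the cortical paired-pulse recovery scale.

With tau_rise = 1 ms and a 1 ms pulse, a single presynaptic spike
consumes `1 - e^{-1} ≈ 63 %` of the available resource: depression is
rapid (a few spikes into a tone the pathway is spent) and recovery slow,
which is the entire SSA mechanism.

**Heterogeneity.**  At network construction every synapse's parameters
(time constants, pulse duration, weight, reversal potential) are
independently multiplied by log-normal factors with log-mean 0 and
log-sd 0.1 (~10 % CV).  The median of every jittered parameter equals
its nominal value and signs are preserved.  Neuron parameters are not
jittered.

### Architectures

* **AB** — each of 48 B units receives one depressing synapse from a
  distinct Poisson unit in every sub-population (|A| = 96·48).  A single
  feed-forward layer of depressing synapses; SSA read out in B.
* **ABC** — adds 48 inhibitory C units.  A→C duplicates the A→B
  connectivity (C unit *j* reads the same Poisson column as B unit *j*)
  with non-depressing synapses; each B unit receives 16 inhibitory
  synapses from C units sampled without replacement.  The delayed
  shunting inhibition suppresses spontaneous and tonic stimulus-driven
  activity, leaving a near-binary onset response (with the shipped
  calibration, ~93 % of tone responses carry 0 or 1 spike per unit in a
  100 ms onset window).
* **ABD** — adds 48 D units receiving all-to-all depressing synapses
  from B (no inhibition; `low_spontaneous` noise).  Two depressing
  layers in series: when a single standard repeats, B is silent, the
  B→D synapses stay recovered, and a deviant propagates to D; when many
  equiprobable standards keep B active, B→D is depressed and the same
  deviant dies out — novelty, not mere rarity.

Synaptic delays are zero; in the clock-driven engine a spike reaches its
postsynaptic targets at the next 0.1 ms step.

## Numerics

Fixed-step clock-driven integration, default dt = 0.1 ms, with all
populations and synapses updated each step in a fixed order (input
draws, synapse transfers, noise, neurons).  Scheme choices:

* **Synapses: exponential transfers.**  Each state's outflow over a step
  is integrated exactly for its own rate (`x (1 - e^{-h/tau})`, with `h`
  the within-step pulse overlap for the R→E transfer) and the three
  transfers are applied simultaneously, so R + E + I is conserved to
  float rounding for arbitrary spike trains and any step size.  Plain
  forward Euler was rejected: at dt = 0.1 ms it misses the
  single-pulse peak effective fraction by ~8 % relative to a 10×-refined
  integration, while the exponential-transfer scheme is within 1 %.
* **Neurons: Heun (explicit trapezoid).**  Forward Euler accumulates
  >1 ms spike-time error within a few spikes; Heun keeps each spike time
  on a frozen 500 ms suprathreshold trace within 1 ms of a dt/100
  oracle and the 1 s spike count within ±1.  The exponential
  spike-initiation argument is clamped at +30 to avoid overflow; the
  clamp only engages during the upswing, after the crossing is already
  inevitable.
* **OU noise: exact discretization** (`g ← g0 + (g-g0)e^{-dt/tau} +
  sigma sqrt(1-e^{-2dt/tau}) N`), distributionally exact at any step.
* **Degenerate inputs.**  Non-finite membrane state aborts the run with
  a numerical-blow-up error; spike-buffer overflow triggers a retry with
  a larger buffer; an all-zero-weight network runs fine (noise-only).

The vectorised kernel (numba) implements the identical update rules as
the scalar reference functions in `ssanet.neurons` / `ssanet.synapses`;
the test-suite pins this equivalence with a fully deterministic
configuration (saturated input probabilities, zero noise sigma, no
jitter) in which the kernel's spike times must match a pure-Python
replay built from the scalar functions.

**Randomness.**  Each simulation consumes one legacy MT19937 stream
seeded per call, with a fixed draw order; recording consumes no
randomness.  Experiment runners derive per-condition seeds by hashing
the root seed with the condition labels (SHA-256, reduced below 2^31),
so any condition can be replayed in isolation and adding conditions
never perturbs existing ones.

## Calibration

The model's pathway weights are not derivable from first principles;
they were selected with the shipped calibration workflow
(`ssanet.experiments.run_calibration`, also exposed as `ssanet
calibrate`), which sweeps one pathway weight holding the others fixed
and records the median SSA index (SI) in the high-SSA oddball
condition.  Selected operating point (nominal full-scale values, stored
in `defaults.yaml`):

| parameter | value | selection criterion |
|---|---|---|
| sigma_e (high-spontaneous) | 23.4375 nS | ~5 Hz spontaneous AdEx rate |
| w(A→B) | 10 nS | SI on its plateau; B firing rates realistic |
| w(A→C) | 5 nS | moderate tonic C activity (~20 Hz driven) |
| w(C→B) | 30 nS | ≥90 % binary tone responses; SI stable, control null |
| w(B→D) | 12 nS | D novelty excess positive at all tested Δf |

Increasing w(A→B) beyond the plateau raises spike counts but not SI;
the SI is robust to ±20 % weight changes (the calibration sweep's
factors 0.5/1/2 bracket this).

## Scaling

Full-scale simulations (48 units per AdEx population, 96/144
sub-populations, 800–1000-tone sequences) are supported but slow on one
core, so the shipped experiment defaults and the test batteries run a
scaled-down configuration: 8 units per AdEx population, 24 (two-tone)
or 36 (multi-tone) sub-populations, 100–200-tone sequences.  Two rules
keep the scaled model in the same operating regime:

* populations are homogeneous and unconnected within themselves, so
  reducing the unit count only reduces sampling resolution (each B unit
  owns its private column of Poisson inputs);
* reducing the sub-population count reduces the number of synapses
  converging on each unit, so input-pathway weights are multiplied by
  `96/n_subpop` (or `144/n_subpop`) and B→D weights by `48/n_b`,
  preserving each unit's total synaptic conductance.

The inhibitory in-degree is capped at the C-population size (8 at scale,
16 at full scale).

## Statistical design of the test batteries

**Replicate-level significance tests.**  Within one simulated oddball
run, all units experience the *same* realization of the random
standard/deviant pattern.  Any finite sequence realization carries a
small idiosyncratic bias (e.g. deviant slots landing after atypically
long runs), which is therefore *common to all units*; a unit-level
signed-rank test treats it as n independent confirmations and rejects a
true null far above the nominal rate.  The bias shrinks as
1/sqrt(n_tones) — but so does the per-unit noise, so longer sequences do
not restore the test's validity.  The shipped significance checks (SSA
present in the high-SSA condition; SSA absent in the equiprobable
control) therefore use six *independent sequence-pair replicates* of 100
tones each, with the per-replicate median neuron-specific SI as the unit
of analysis — these replicates are genuinely independent, and six of
them give a smallest attainable two-sided signed-rank p of 0.031.
Orderings (SI versus Δf, deviant probability, ISI, switching metric) use
single fixed-seed runs per condition, where the effect sizes dwarf the
realization noise.

**Analysis windows.**  Per-tone spike counts default to the full
onset-to-onset epoch in the library; the experiment batteries use a
100 ms onset window, which captures the ABC model's phasic response and
the AB model's tonic response while excluding the long silent period
whose spontaneous spikes would dilute the SI.  Both conventions are
supported everywhere.

**Problem sizes.**  The trend batteries use 100–200-tone sequences at
500 ms inter-onset intervals (250 ms for the grid-mode and
many-standards protocols, matching their faster presentation), chosen
so the full suite completes in minutes on one core while every ordering
retains a comfortable margin over its seed-to-seed variability.

## What the synthetic stimuli do and do not emulate

The generators reproduce the *structure* of the experimental protocols
exactly — isochronous tone trains, frequency-swapped oddball pairs
sharing one role pattern, two-state Markov chains with the scaled
switching metric `s = q_DS / min(1, (1-p)/p)` (0 = frozen, 1 = maximal
switching, with the i.i.d. oddball recovered at `s = 1 - p` for
p ≤ 0.5), balanced many-standards controls with deviants pinned to their
oddball slots.  They do not emulate acoustics: there is no cochlear
front-end, no intensity or duration tuning, and "frequency" is an
abstract octave coordinate feeding the tuning curves.  Passing tests
show that convergent depressing synapses reproduce the catalogued SSA
phenomenology under these idealized drives, not that the model fits any
particular recorded neuron.

## Known limitations

* Forward-model only: no fitting interface to physiological spike
  trains.
* Tone-frequency is the only stimulus feature; intensity, duration and
  modulation tuning would need their own input populations.
* The one-dt synaptic latency is a numerical device, not a biological
  conduction delay.
* No facilitation, NMDA/GABA_B kinetics, or stochastic vesicle release.
* The four-population variant with both inhibition and a second
  depressing layer, and chains with more than two Markov states, are
  out of scope.
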