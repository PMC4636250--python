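# Model and methods

## The question the model answers

In the dentate gyrus in vivo, brief high-frequency stimulation of the
medial perforant path (MPP) potentiates the stimulated synapses and
simultaneously depresses the non-stimulated lateral perforant path (LPP)
— and the outcome depends sharply on the temporal pattern of the
tetanus: 400 Hz delta-burst stimulation (400-DBS) works well, a 400 Hz
theta-burst (400-TBS) moderately, the standard 100 Hz theta-burst
(100-TBS) hardly at all.  `gcplast` shows that a single synapse-local
timing rule plus one cell-global homeostatic variable, embedded in a
morphological granule-cell model driven by ongoing afferent activity, is
sufficient to generate this pattern.

## Granule-cell model

**Morphology.** Soma (16.8 µm long and wide) with two symmetric
dendritic branches; each branch traverses a 50 µm granule-cell-layer
(GCL) section and 150 µm inner/middle/outer molecular layer (IML / MML /
OML) sections, all 3 µm in diameter.  Full discretization: 125
compartments (1 soma, 5 per GCL section, 19 per molecular-layer
section); reduced mode: one compartment per section (9 total), used for
parameter scans and the routine test runs.  MPP synapses (150) are
placed uniformly at random on MML compartments of both branches, LPP
synapses (150) on OML compartments.

**Membrane mechanisms.**  Channel *densities* are data (a JSON registry
keyed by source name); channel *kinetics* are code.  Two sources ship:

- `fallback-hh` (default): HH-style Na and fast delayed-rectifier K in
  all compartments, plus a generic high-threshold Ca channel and a
  Ca-gated SK channel in the dendritic layers; passive leak 5·10⁻⁵
  S/cm², C_m 1 µF/cm², R_a 210 Ω·cm, E_leak −70 mV.
- `modeldb-51781`: per-layer densities for the nine-channel roster (Na,
  fast/slow delayed rectifier, A-type K, T/N/L-type Ca, SK, BK)
  transcribed from the published dentate granule-cell model this
  morphology follows.  Because the transcription could not be verified
  against the original source files, results with this source are
  labelled conditional throughout.

The kinetics are reconstructions tuned to reproduce the firing
behaviors the plasticity mechanism depends on, rather than fitted rate
functions from the original model: resting potential ≈ −70 mV with zero
input indefinitely; somatic spiking under current steps but not when
somatic Na is blocked (dendritic Na supports back-propagation without
being self-regenerative); **strong refractoriness during 400 Hz
volleys** (sodium-inactivation: h-gate midpoint −52 mV, slope 4,
τ_h ≈ 12 ms near rest, ~2 ms depolarized; the published cell fired 2–4
spikes per 10-pulse burst, this reconstruction 4–5); **faithful
~1 spike per pulse at 100 Hz**; and a back-propagating action potential
that crosses −37 mV in the OML *only* when dendritic Na/Ca channels are
active (passively it peaks near −42 mV there).  These behaviors, not
any weight-change outcome, were the calibration targets for the channel
parameters.

Channel blocks are per-layer conductance multipliers; a block scheduled
mid-run takes effect at the next integration step.

**Synapses.**  Difference-of-exponentials conductance (rise 0.2 ms,
decay 2.5 ms, reversal 0 mV), peak-normalized so the weight *is* the
peak conductance (µS).  Linear summation; a synapse receiving two
spikes within one integration step counts one (streams are merged with
a dt-wide dedup window).

**Numerics.**  Backward-Euler integration of the cable equation, dt =
0.2 ms by default (0.1 ms supported).  Gates advance by exponential
(Rush–Larsen) updates at the start-of-step voltage; the voltage solve is
an O(N) Hines elimination on the tree (compartments ordered
parent-before-child).  Backward Euler keeps spike *counts* and rates
dt-invariant but carries a small per-period phase drift (~0.3%); the
dt-convergence contract is therefore stated on counts, rates and
first-spike latency, and — for the quantity that matters — on the
plasticity outcomes, which agree at dt = 0.1 vs 0.2 ms within a few
percentage points when α is rescaled (see below).  A Crank–Nicolson
variant was evaluated and rejected: its extrapolation step rings on the
stiff action-potential upstroke and made the firing rate *more*
dt-dependent.

## Afferent drive

Every synapse receives an independent quasi-periodic train,
`ISI = (1−noise)·ISI₀ + Exponential(mean = noise·ISI₀)`, ISI₀ = 125 ms,
noise = 0.05 → mean rate exactly 8 Hz at any noise, perfectly periodic
at noise = 0, Poisson at noise = 1, and an absolute ISI floor of
(1−noise)·ISI₀.  Trains are phase-locked only on average (shared ISI₀,
independent jitter).  Protocol presets:

| preset | structure | pulses |
| --- | --- | --- |
| 400-DBS | 10 pulses @ 400 Hz × 5 bursts @ 1 Hz × 10 repeats @ 60 s | 500 |
| 100-TBS | 4 pulses @ 100 Hz × 10 bursts @ 5 Hz × 8 repeats @ 10 s | 320 |
| 400-TBS | 4 pulses @ 400 Hz × 10 bursts @ 5 Hz × 8 repeats @ 10 s | 320 |

Protocol pulses are superimposed on (not substituted for) the
spontaneous trains of a seeded random subset of medial synapses
(default 60%); the subset is drawn fresh per replicate.  Spontaneous
firing is never altered by the tetanus.  The lateral-off control
removes all lateral spikes from the HFS onset onward.

## Plasticity rule

**Events.**  Two detectors: local post events are upward crossings of
−37 mV of the compartment voltage at the synapse, with a 5 ms debounce
(one action-potential width; prevents multi-counting one
depolarization); somatic spikes are upward 0 mV crossings at the soma.
Local events drive pairing; somatic spikes drive homeostasis.

**Pairing (pre-centered nearest neighbor).**  For each presynaptic
spike only the latest post event at-or-before it and the earliest post
event strictly after it are considered:

    w ← w (1 + Δw_p − Δw_d),  Δw_p = A_p e^(−Δt/τ_p) (Δt>0),  Δw_d = A_d e^(Δt/τ_d) (Δt<0)

with τ_p = 20 ms, τ_d = 70 ms.  Timing of application is causal: the
depression term applies at the pre spike (its preceding event is already
known); the potentiation term applies when the next post event arrives,
using the amplitudes current at *that* time, and lapses if none arrives
within 5·τ_p (where the contribution would be < e⁻⁵ A_p anyway).  A
coincident pair (Δt = 0) contributes to neither window.  One post event
may serve as nearest neighbor for many pre spikes (no consumption).
Weights are clamped to ±100% of each synapse's baseline
(`max_change = 1`; the upper bound is a model assumption, the symmetric
lower bound a configuration choice) and stay strictly positive.

**Homeostasis (fast BCM-like metaplasticity).**  The somatic
spike-count average follows, per step,
⟨c⟩ ← ⟨c⟩·e^(−dt/τ) + (α/τ)·dt·[spike], the exact one-step form of
⟨c⟩ = (α/τ)∫c(t′)e^(−(t−t′)/τ)dt′ with a per-step spike indicator.
τ = 60 s; α·dt is held constant (α = 2500 at dt = 0.2 ms, 5000 at
0.1 ms), so the steady state under rate r is α·dt·r, independent of dt.
Amplitudes slide every step as A_p = A_p(0)/⟨c⟩, A_d = A_d(0)·⟨c⟩
(A_p(0) = 0.003, A_d(0) = 0.001), conserving A_p·A_d exactly.  A floor
⟨c⟩ ≥ 10⁻³ keeps A_p finite at simulation start; in addition plasticity
is disabled during a warm-up of max(60 s, τ) while ⟨c⟩ builds up.
Either amplitude can be frozen at its initial value (homeostasis-off
controls).

**Baseline calibration.**  Baseline weights are set by seeded log-space
bisection so the 8 Hz spontaneous drive at all 300 synapses fires the
soma at the homeostatic fixed point 1000/(α·dt) Hz = 2 Hz, where
⟨c⟩ = 1 and the amplitudes equal their initial values (flat baseline).
The calibrated weight (~0.19 nS with the default source) is recorded in
every run manifest.

## Experiment timeline and measurement

warm-up (plasticity off) → 120 s baseline → protocol → 600 s post.
Per-synapse changes are (w_final − w_baseline)/w_baseline × 100 with
baseline = the 60 s before HFS and final = the last 120 s of the run
(the weight series plateaus well before this window; e.g. the lateral
mean moves < 1 pp over the final 300 s of a 400-DBS run).  Pathway
values are arithmetic means over synapses, reported as mean ± SD over
replicates (3 by default; 10 for robustness sweeps).  Distances for
weight-vs-distance plots are path distances along the dendrite from the
soma.

## What the defaults reproduce (and what they don't)

With the default `fallback-hh` source, reduced morphology, and the
parameters above, the closed-loop experiments give (mean ± SD, 3 runs,
60% tetanization): 400-DBS +46 ± 1% MPP / −20 ± 1% LPP; 400-TBS
+14…+18% / −6…−8%; 100-TBS +2…+5% / −1…−2%; reference values from the
in vivo-constrained modelling study this package follows are
+45.3 ± 4.4 / −30.6 ± 1.5, +25.0 ± 2 / −20.7 ± 1.6 and +5.3 ± 0.3 /
−6.5 ± 0.3 respectively.  The qualitative structure — protocol
ordering on both pathways, LTP onset before LTD onset, loss of lateral
LTD without lateral activity, persistence of medial LTP (but not
lateral LTD) under dendritic Na/Ca block, larger |LTD| than LTP at 100%
tetanization, increased 100-TBS LTP when A_p is frozen — reproduces
robustly.  Quantitatively, medial LTP and the 100-TBS weakness match
the reference values; the *magnitude* of lateral LTD saturates near
−21% instead of −31% (identically in 9- and 125-compartment modes), a
gap we attribute to the reconstructed channel kinetics and leave open
rather than tune away.

Two secondary mechanistic claims of the reference study also come out
differently here: total somatic spiking during HFS is slightly *higher*
for 400-TBS than 100-TBS (the ordering of plasticity outcomes is
nevertheless preserved, because the pre→post timing statistics
discriminate the protocols as well as the firing rate does), and
slowing the integration period to 10 min distorts the 100-TBS outcome
by erosion rather than inflation.

## Problem sizes

Routine runs (tests, examples, scans) use the 9-compartment reduced
mode — the same reduction the robustness scans of the reference study
use — with full protocol timelines (a 400-DBS run spans ~22 simulated
minutes); the 125-compartment mode is available through
`ExperimentSpec(reduced=False)` and the CLI's `--full-morphology` and
gives the same headline outcomes (+46.3/−20.9 vs +45.3/−20.4 in one
matched 400-DBS run).

## Known limitations

- No synaptic depression/facilitation, stochastic channel gating,
  temperature dependence, or network feedback (inhibition is absent).
- Channel kinetics are behavior-matched reconstructions, not verified
  transcriptions; quantitative claims with `modeldb-51781` are
  conditional, and that source is currently not tuned to the
  burst-following targets (it is provided as data + machinery).
- The generator models stationary spontaneous activity; real afferent
  rates fluctuate and are modulated by behavioral state, so passing
  tests demonstrate the mechanism, not in vivo variability.
- Event times inside the coupled kernel are resolved to the integration
  step (0.2 ms), which is ≤ 1% of either STDP window.
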