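# gcplast

**Voltage-based STDP with fast BCM-like metaplasticity in a compartmental
dentate granule cell.**

`gcplast` models a puzzle from the dentate gyrus of behaving rats: brief
high-frequency stimulation (HFS) of the medial perforant path produces
long-term potentiation (LTP) of the tetanized synapses *and*, at the same
time, long-term depression (LTD) of the neighbouring, non-tetanized lateral
perforant path — and the sizes of both effects depend strongly on the
temporal pattern of the tetanus.  400 Hz delta-burst stimulation (400-DBS)
is highly effective, a 400 Hz theta-burst (400-TBS) less so, and the
classic 100 Hz theta-burst (100-TBS) — a reliable LTP protocol *in vitro*
— produces almost nothing.  The package reproduces this
`400-DBS > 400-TBS > 100-TBS` pattern, and the dependence of the
heterosynaptic LTD on ongoing afferent activity, from three coupled
ingredients:

1. **A reduced-morphology granule cell** (soma + two dendritic branches
   crossing the granule-cell, inner, middle and outer molecular layers;
   125 compartments, or 9 in the reduced scan mode) with active
   conductances, solved with an implicit cable integrator.  150 medial
   synapses terminate on the middle molecular layer, 150 lateral synapses
   on the outer molecular layer.
2. **Ongoing spontaneous input**: every synapse independently fires
   quasi-periodically at 8 Hz, `ISI = (1-noise)·ISI₀ + Exp(noise·ISI₀)`
   with `ISI₀ = 125 ms`, `noise = 0.05`.  HFS pulses are superimposed on
   this background for a (default 60%) random subset of medial synapses.
3. **The plasticity rule.**  Pre-centered nearest-neighbor event-timing
   STDP: each presynaptic spike pairs with the nearest *local* dendritic
   events — upward crossings of −37 mV at the synapse (a back-propagating
   action potential or sufficiently synchronous local depolarization):

   ```
   w ← w (1 + Δw_p − Δw_d)
   Δw_p = A_p exp(−Δt/τ_p)   (Δt = t_post − t_pre > 0)
   Δw_d = A_d exp(+Δt/τ_d)   (Δt < 0)
   ```

   with τ_p = 20 ms, τ_d = 70 ms, and a fast BCM-like homeostasis that
   slides the amplitudes with the recent somatic spike-count average
   ⟨c⟩ = (α/τ)∫c(t′)e^(−(t−t′)/τ)dt′ (τ = 60 s, α·dt = 0.5):

   ```
   A_p(t) = A_p(0)/⟨c⟩ ,   A_d(t) = A_d(0)·⟨c⟩ ,   A_p(0)=0.003, A_d(0)=0.001
   ```

Baseline weights are not free parameters: a seeded calibration routine
sets them so the spontaneous drive fires the soma at ~2 Hz, the fixed
point where ⟨c⟩ = 1 and the amplitudes sit at their initial values.

## Worked example

```bash
python examples/heterosynaptic_ltd.py
```

runs the full 400-DBS protocol (10 × five 10-pulse 400 Hz bursts at 1 Hz,
repeated at 1-min intervals) to 60% of the medial synapses of the reduced
cell and prints:

```
baseline weight: 0.187 nS
tetanized medial synapses:     +45.3 %   (homosynaptic LTP)
non-tetanized medial:          -19.4 %   (heterosynaptic LTD)
lateral pathway:               -20.4 %   (heterosynaptic LTD)
```

Only the synapses that received the tetanus potentiate; every synapse
carrying just the 8 Hz background is depressed, because once the
potentiated input controls somatic spiking the remaining inputs fall
mostly on the post-before-pre (depressing) side of the timing windows.
Other examples: `spontaneous_trains.py` (input statistics),
`burst_following.py` (somatic refractoriness at 400 Hz vs faithful 100 Hz
following), `standalone_plasticity.py` (the rule on bare event streams).

The same experiments are scriptable from the shell:

```bash
gcplast list                      # scenario catalog (protocol comparisons,
gcplast run fig3 --seed 1         #  channel blocks, robustness sweeps ...)
gcplast report                    # compare against stored reference values
```

## Layout

| path | contents |
| --- | --- |
| `src/gcplast/inputs.py` | spontaneous trains, protocol presets, drive assembly |
| `src/gcplast/plasticity.py` | the STDP/metaplasticity rule (also standalone on text streams) |
| `src/gcplast/morphology.py`, `mechanisms.py`, `cell.py` | granule-cell model |
| `src/gcplast/_kernel.py` | numba cable solver coupled to the plasticity rule |
| `src/gcplast/engine.py` | calibration + closed-loop experiments |
| `src/gcplast/scenarios.py`, `cli.py` | scenario catalog, reports, CLI |
| `docs/methods.md` | model description, parameters, numerical choices, limitations |
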