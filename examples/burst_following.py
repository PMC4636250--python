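"""Somatic firing during one high-frequency burst.

Delivers a single 400 Hz 10-pulse burst or a 100 Hz 4-pulse burst to all
medial-path synapses at calibrated baseline weights and counts somatic
spikes: refractoriness limits the 400 Hz response while the theta-burst
pulses are followed faithfully — the firing difference that drives the
protocol dependence of plasticity.
"""

import numpy as np

import gcplast
from gcplast.engine import calibrate_baseline_weight, replace_weights
from gcplast.inputs import EventStreams
from gcplast.plasticity import PlasticityParams, detect_events

cell = gcplast.build_cell(reduced=False)
cell_r = gcplast.build_cell(reduced=True)
pop_r = gcplast.attach_synapses(cell_r, seed=902101)
w = calibrate_baseline_weight(cell_r, pop_r, PlasticityParams())
print(f"calibrated baseline weight: {w * 1e3:.3f} nS (target ~2 Hz spontaneous rate)")

pop = replace_weights(gcplast.attach_synapses(cell, seed=902101), w)

for freq, npulse in ((400, 10), (100, 4)):
    pulses = 50.0 + np.arange(npulse) * 1000.0 / freq
    times = [
        pulses.copy() if pop.pathway[i] == "medial" else np.empty(0)
        for i in range(pop.n)
    ]
    drive = EventStreams(times=times, tetanized=np.zeros(pop.n, bool))
    tr = gcplast.integrate(
        cell, pop, drive, duration=150.0, dt=0.2,
        probes=[("soma", 0.5), ("oml1", 0.5)],
    )
    spikes = detect_events(tr[0].times, tr[0].v, 0.0, debounce=2.0)
    oml_events = detect_events(tr[1].times, tr[1].v, -37.0, debounce=5.0)
    print(
        f"{freq} Hz x {npulse} pulses -> {len(spikes)} somatic spikes, "
        f"{len(oml_events)} OML threshold crossings"
    )
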