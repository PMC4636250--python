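"""Homosynaptic LTP with concurrent heterosynaptic LTD (headline experiment).

Runs the full 400 Hz delta-burst protocol to 60% of the medial-path
synapses of the reduced granule cell, on top of ongoing 8 Hz spontaneous
activity at all 300 synapses, and reports the pathway weight changes.
Takes ~1 minute.
"""

from gcplast.engine import ExperimentSpec, measure_pathway_change, run_experiment

spec = ExperimentSpec(protocol="400-DBS", tetanized_fraction=0.6, n_runs=1, seed=11)
result = run_experiment(spec)[0]

med, _ = measure_pathway_change(result, "medial", tetanized_only=True)
med_nt, _ = measure_pathway_change(result, "medial", tetanized_only=False)
lat, _ = measure_pathway_change(result, "lateral")

print(f"baseline weight: {result.manifest['baseline_weight_uS'] * 1e3:.3f} nS")
print(f"tetanized medial synapses:    {med:+6.1f} %   (homosynaptic LTP)")
print(f"non-tetanized medial:         {med_nt:+6.1f} %   (heterosynaptic LTD)")
print(f"lateral pathway:              {lat:+6.1f} %   (heterosynaptic LTD)")
print(
    "\nOnly the tetanized synapses potentiate; every synapse that received "
    "just the spontaneous 8 Hz activity is depressed, because after LTP the "
    "potentiated input controls somatic spiking and the remaining inputs "
    "fall into the post-before-pre (depressing) side of the timing windows."
)
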