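"""The plasticity rule on hand-built event streams (no biophysics).

One synapse receives five presynaptic spikes around three local
postsynaptic events; the somatic spike train drives the homeostatic
amplitudes.  Prints the final weight and compares the pre-centered
nearest-neighbor contributions pair by pair.
"""

import numpy as np

from gcplast.plasticity import PlasticityParams, pair_nearest_neighbor, run_on_streams

pre = np.array([10.0, 35.0, 60.0, 61.0, 95.0])
post = np.array([20.0, 50.0, 90.0])
soma = post.copy()  # here every local event is also a somatic spike

params = PlasticityParams()
res = run_on_streams([pre], [post], soma, duration=120.0, dt=0.2, params=params)

print("pre spike -> (dt_before, dt_after) nearest-neighbor pairing:")
for t in pre:
    print(f"  t_pre={t:5.1f} ms -> {pair_nearest_neighbor(t, post)}")

print(f"\nfinal weight: {res['state'].w[0]:.6f} (baseline 1.0)")
print(f"final <c>={res['c_avg'][-1]:.4f}  A_p={res['a_p'][-1]:.5f}  A_d={res['a_d'][-1]:.6f}")
print(
    "\nSpikes preceding an event potentiate (A_p e^{-dt/tau_p}); spikes "
    "following one depress (A_d e^{dt/tau_d}); the amplitudes slide with "
    "the somatic spike-count average and their product stays at "
    f"{params.a_p0 * params.a_d0:g}."
)
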