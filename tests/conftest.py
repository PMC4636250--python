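"""Shared fixtures: small cells and cached closed-loop runs.

The closed-loop protocol runs are expensive (tens of seconds each), so
they are computed once per session and shared by every test that needs
them.  All randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

from gcplast.engine import ExperimentSpec, run_experiment

#: Seeds for the replicated protocol-comparison runs.
PROTO_SEEDS = (11, 23, 42)


@pytest.fixture(scope="session")
def reduced_cell():
    import gcplast

    return gcplast.build_cell(reduced=True)


@pytest.fixture(scope="session")
def full_cell():
    import gcplast

    return gcplast.build_cell(reduced=False)


@pytest.fixture(scope="session")
def calibrated_weight(reduced_cell):
    """Baseline weight (µS) giving ~2 Hz under spontaneous drive (9-seg mode)."""
    import gcplast
    from gcplast.engine import calibrate_baseline_weight
    from gcplast.plasticity import PlasticityParams

    pop = gcplast.attach_synapses(reduced_cell, seed=902101)
    return calibrate_baseline_weight(reduced_cell, pop, PlasticityParams())


@pytest.fixture(scope="session")
def protocol_runs(calibrated_weight):
    """One run per (protocol, seed): the core protocol-comparison dataset."""
    out = {}
    for proto in ("400-DBS", "100-TBS", "400-TBS"):
        for seed in PROTO_SEEDS:
            spec = ExperimentSpec(
                protocol=proto, n_runs=1, seed=seed, baseline_weight=calibrated_weight
            )
            out[(proto, seed)] = run_experiment(spec)[0]
    return out


@pytest.fixture(scope="session")
def lateral_off_pair(calibrated_weight):
    """Matched 400-DBS runs with and without ongoing lateral activity."""
    common = dict(
        protocol="400-DBS",
        tetanized_fraction=1.0,
        n_runs=1,
        seed=3,
        baseline_weight=calibrated_weight,
    )
    on = run_experiment(ExperimentSpec(**common))[0]
    off = run_experiment(ExperimentSpec(**common, lateral_off_at_hfs=True))[0]
    return on, off
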