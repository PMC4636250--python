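"""Named experiment scenarios and report generation.

Each scenario resolves to one or more complete
:class:`~gcplast.engine.ExperimentSpec` objects: the headline protocol
comparisons, the mechanistic controls (lateral activity off, channel
blocks, frozen homeostasis), and the robustness sweeps over tetanized
fraction, input noise, STDP window widths, amplitude ratio, dendritic
threshold and metaplasticity integration period.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .inputs import get_protocol
from .engine import ExperimentSpec, measure_pathway_change, run_experiment, weight_vs_distance
from .plasticity import PlasticityParams

__all__ = ["SCENARIOS", "scenario_specs", "run_scenario", "summarize", "load_reference_values"]


def _p(**kw) -> PlasticityParams:
    return PlasticityParams(**kw)


def _specs_fig8() -> dict[str, ExperimentSpec]:
    out = {}
    for tau_min in (0.1, 1.0, 10.0, 20.0):
        for proto in ("400-DBS", "100-TBS", "400-TBS"):
            key = f"tau{tau_min:g}min_{proto}"
            out[key] = ExperimentSpec(protocol=proto, plasticity=_p(tau_c=tau_min * 60.0))
    return out


def _specs_fig7() -> dict[str, ExperimentSpec]:
    block = ("na", "cat", "can", "cal")
    layers = ("GCL", "IML", "MML", "OML")
    return {
        f"block_{proto}": ExperimentSpec(
            protocol=proto, block_channels=block, block_layers=layers
        )
        for proto in ("400-DBS", "100-TBS", "400-TBS")
    }


#: Scenario registry: name -> (description, builder returning {label: spec}).
SCENARIOS: dict[str, tuple[str, callable]] = {
    "fig1b_top": (
        "400-DBS to 100% of medial synapses",
        lambda: {"dbs400_full": ExperimentSpec(protocol="400-DBS", tetanized_fraction=1.0)},
    ),
    "fig1b_mid": (
        "400-DBS to 60% of medial synapses",
        lambda: {"dbs400_60pct": ExperimentSpec(protocol="400-DBS")},
    ),
    "fig1b_bottom": (
        "400-DBS with lateral spontaneous activity off at HFS onset",
        lambda: {
            "dbs400_lateral_off": ExperimentSpec(
                protocol="400-DBS", tetanized_fraction=1.0, lateral_off_at_hfs=True
            )
        },
    ),
    "fig2a": (
        "100-TBS to 60% of medial synapses",
        lambda: {"tbs100_60pct": ExperimentSpec(protocol="100-TBS")},
    ),
    "fig2b": (
        "400-TBS to 60% of medial synapses",
        lambda: {"tbs400_60pct": ExperimentSpec(protocol="400-TBS")},
    ),
    "fig3": (
        "Summary triplet: all three protocols at 60% tetanization",
        lambda: {
            "dbs400_60pct": ExperimentSpec(protocol="400-DBS"),
            "tbs100_60pct": ExperimentSpec(protocol="100-TBS"),
            "tbs400_60pct": ExperimentSpec(protocol="400-TBS"),
        },
    ),
    "fig4": (
        "Spike-count average and amplitude dynamics per protocol",
        lambda: {
            f"dynamics_{p}": ExperimentSpec(protocol=p, n_runs=1)
            for p in ("400-DBS", "100-TBS", "400-TBS")
        },
    ),
    "fig5": (
        "Membrane voltage at soma and MML dendrite during one HFS train",
        lambda: {
            f"trace_{p}": ExperimentSpec(
                protocol=get_protocol(p, n_repeats=1),
                n_runs=1,
                warmup_s=5.0,
                baseline_s=5.0,
                post_s=2.0,
                probes=(("soma", 0.5), ("mml1", 0.5)),
            )
            for p in ("400-DBS", "100-TBS", "400-TBS")
        },
    ),
    "fig6": (
        "Early-HFS weight evolution (LTP precedes LTD)",
        lambda: {
            f"early_{p}": ExperimentSpec(protocol=p, n_runs=1, record_every_s=0.2)
            for p in ("400-DBS", "400-TBS")
        },
    ),
    "fig7": ("Dendritic Na/Ca channel block during HFS, three protocols", _specs_fig7),
    "fig8": ("Metaplasticity integration period 0.1/1/10/20 min", _specs_fig8),
    "s1": (
        "Tetanized fraction 20/60/100%",
        lambda: {
            f"frac{int(f*100)}": ExperimentSpec(protocol="400-DBS", tetanized_fraction=f, n_runs=10)
            for f in (0.2, 0.6, 1.0)
        },
    ),
    "s2": (
        "Input noise 0/0.01/0.05/1",
        lambda: {
            f"noise{n:g}": ExperimentSpec(protocol="400-DBS", noise=n, n_runs=10)
            for n in (0.0, 0.01, 0.05, 1.0)
        },
    ),
    "s3": (
        "STDP window scan: tau_d 30/70/100 ms at tau_p 20; tau_p 10/20/40 ms at tau_d 70",
        lambda: {
            **{
                f"taud{td:g}": ExperimentSpec(
                    protocol="400-DBS", plasticity=_p(tau_d=td), n_runs=10
                )
                for td in (30.0, 70.0, 100.0)
            },
            **{
                f"taup{tp:g}": ExperimentSpec(
                    protocol="400-DBS", plasticity=_p(tau_p=tp), n_runs=10
                )
                for tp in (10.0, 40.0)
            },
        },
    ),
    "s4": (
        "Initial amplitude ratio A_p:A_d = 1:1 vs 3:1",
        lambda: {
            "ratio1to1": ExperimentSpec(
                protocol="400-DBS", plasticity=_p(a_p0=0.001, a_d0=0.001), n_runs=10
            ),
            "ratio3to1": ExperimentSpec(protocol="400-DBS", n_runs=10),
        },
    ),
    "s5": (
        "Dendritic event threshold -30/-33/-37/-40 mV",
        lambda: {
            f"thresh{int(v)}": ExperimentSpec(
                protocol="400-DBS", plasticity=_p(v_syn_thresh=v), n_runs=10
            )
            for v in (-30.0, -33.0, -37.0, -40.0)
        },
    ),
    "homeostasis_off": (
        "100-TBS with the homeostatic adjustment of A_p frozen",
        lambda: {
            "tbs100_ap_frozen": ExperimentSpec(
                protocol="100-TBS", plasticity=_p(freeze_a_p=True)
            ),
            "tbs100_60pct": ExperimentSpec(protocol="100-TBS"),
        },
    ),
}


def scenario_specs(name: str, **overrides) -> dict[str, ExperimentSpec]:
    """Resolve a scenario name to its labelled experiment specs."""
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    _, builder = SCENARIOS[name]
    specs = builder()
    if overrides:
        plast_fields = {f.name for f in dataclasses.fields(PlasticityParams)}
        spec_over = {k: v for k, v in overrides.items() if k not in plast_fields}
        plast_over = {k: v for k, v in overrides.items() if k in plast_fields}
        new = {}
        for label, spec in specs.items():
            if plast_over:
                spec = replace(spec, plasticity=replace(spec.plasticity, **plast_over))
            new[label] = replace(spec, **spec_over)
        specs = new
    for label, spec in specs.items():
        if spec.noise == 0.0:
            warnings.warn(
                f"{label}: noise = 0 makes all afferents perfectly synchronous; "
                "the two pathways may co-potentiate or co-depress",
                stacklevel=2,
            )
    return specs


def run_scenario(name: str, overrides: dict | None = None, out_dir=None) -> dict:
    """Execute a scenario; returns {label: {specs, results, summary rows}}.

    If ``out_dir`` is given, writes per-label run manifests (JSON), the
    summary table (CSV) and plot-ready weight series (CSV).
    """
    specs = scenario_specs(name, **(overrides or {}))
    bundle = {}
    rows = []
    for label, spec in specs.items():
        results = run_experiment(spec)
        entry = {"spec": spec, "results": results}
        for pathway in ("medial", "lateral"):
            tet = True if pathway == "medial" and spec.protocol is not None else None
            mean, sd = measure_pathway_change(results, pathway, tetanized_only=tet)
            rows.append(
                {
                    "scenario": name,
                    "label": label,
                    "pathway": pathway,
                    "tetanized_only": bool(tet),
                    "pct_change_mean": mean,
                    "pct_change_sd": sd,
                    "n_runs": spec.n_runs,
                    "mechanism_source": spec.mechanism_source,
                }
            )
        bundle[label] = entry
    table = pd.DataFrame(rows)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / f"{name}_summary.csv", index=False)
        for label, entry in bundle.items():
            res = entry["results"][0]
            with open(out / f"{name}_{label}_manifest.json", "w") as fh:
                json.dump(res.manifest, fh, indent=2, default=str)
            series = pd.DataFrame(
                {
                    "time_s": res.times_s,
                    "medial_mean_uS": res.w[:, res.pathway == "medial"].mean(axis=1),
                    "lateral_mean_uS": res.w[:, res.pathway == "lateral"].mean(axis=1),
                    "c_avg": res.c_avg,
                    "a_p": res.a_p,
                    "a_d": res.a_d,
                }
            )
            series.to_csv(out / f"{name}_{label}_series.csv", index=False)
    return {"bundle": bundle, "summary": table}


def load_reference_values() -> dict:
    path = resources.files("gcplast.data").joinpath("reference_values.json")
    return json.loads(path.read_text())


def summarize(bundles: dict, tolerance_pp: float = 3.0, sd_factor: float = 3.0) -> pd.DataFrame:
    """Compare scenario outcomes against the stored reference values.

    ``bundles`` maps label -> list of SimulationResult (as produced by
    :func:`run_scenario` entries).  A row passes when the simulated mean
    lies within ``max(tolerance_pp, sd_factor * reference SD)`` of the
    reference.  Rows from the simplified fallback mechanism source are
    marked conditional.
    """
    ref = load_reference_values()["values"]
    rows = []
    for label, results in bundles.items():
        if label not in ref or not results:
            continue
        source = results[0].manifest["mechanism_source"]
        for pathway, (ref_mean, ref_sd) in ref[label].items():
            tet = True if pathway == "medial" else None
            mean, sd = measure_pathway_change(results, pathway, tetanized_only=tet)
            tol = max(tolerance_pp, sd_factor * ref_sd)
            rows.append(
                {
                    "label": label,
                    "pathway": pathway,
                    "simulated_mean": mean,
                    "simulated_sd": sd,
                    "reference_mean": ref_mean,
                    "reference_sd": ref_sd,
                    "tolerance": tol,
                    "pass": bool(abs(mean - ref_mean) <= tol),
                    "conditional": source != "modeldb-51781",
                }
            )
    return pd.DataFrame(rows)
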