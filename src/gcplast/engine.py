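"""Closed-loop experiments: baseline -> tetanization -> follow-up.

A run couples the compartmental cell, the afferent drive and the
plasticity rule over a timeline

    warm-up (plasticity off, ⟨c⟩ equilibrates) ->
    baseline (plasticity on) -> HFS protocol -> post period,

with ongoing spontaneous activity at every synapse throughout.  Baseline
synaptic weights are not free parameters: they are calibrated (seeded
bisection) so the spontaneous drive produces the target somatic rate —
2 Hz at the default α·dt, which puts the spike-count average at its
fixed point ⟨c⟩ = 1 and the STDP amplitudes at their initial values.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from scipy import stats

from . import _kernel, __name__ as _pkgname
from .cell import CellModel, SynapsePopulation, attach_synapses, build_cell
from .inputs import EventStreams, ProtocolSpec, SpikeTrainSpec, assemble_drive, get_protocol
from .plasticity import PlasticityParams

__all__ = [
    "ExperimentSpec",
    "SimulationResult",
    "run_experiment",
    "run_single",
    "calibrate_baseline_weight",
    "measure_pathway_change",
    "weight_vs_distance",
]

_ALL_LAYERS = ("GCL", "IML", "MML", "OML")


@dataclass(frozen=True)
class ExperimentSpec:
    """Complete description of one plasticity experiment."""

    protocol: str | ProtocolSpec | None = "400-DBS"
    tetanized_fraction: float = 0.6
    noise: float = 0.05
    isi0: float = 125.0
    dt: float = 0.2  # ms
    warmup_s: float | None = None  # None -> max(60 s, tau_c): ⟨c⟩ needs ~one integration period
    baseline_s: float = 120.0
    post_s: float = 600.0
    n_runs: int = 3
    seed: int = 1
    reduced: bool = True  # 9-compartment mode (full 125-compartment if False)
    mechanism_source: str = "fallback-hh"
    n_medial: int = 150
    n_lateral: int = 150
    baseline_weight: float | None = None  # µS; None -> calibrate
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    lateral_off_at_hfs: bool = False
    block_channels: tuple = ()  # channels zeroed at HFS onset
    block_layers: tuple = ()
    record_every_s: float = 1.0
    probes: tuple = ()  # (section, x) pairs for voltage capture
    probe_every_ms: float = 0.4

    def validate(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if min(self.resolved_warmup_s, self.baseline_s, self.post_s) < 0:
            raise ValueError("durations must be non-negative")

    @property
    def resolved_warmup_s(self) -> float:
        if self.warmup_s is not None:
            return self.warmup_s
        return max(60.0, self.plasticity.tau_c)

    def resolve_protocol(self) -> ProtocolSpec | None:
        if self.protocol is None:
            return None
        if isinstance(self.protocol, ProtocolSpec):
            return replace(self.protocol, tetanized_fraction=self.tetanized_fraction)
        return get_protocol(self.protocol, tetanized_fraction=self.tetanized_fraction)


@dataclass
class SimulationResult:
    """One run's recorded series plus the manifest describing it."""

    times_s: np.ndarray  # recording times, s
    w: np.ndarray  # (T, M) weights, µS
    pathway: np.ndarray
    tetanized: np.ndarray
    path_dist: np.ndarray  # µm
    c_avg: np.ndarray
    a_p: np.ndarray
    a_d: np.ndarray
    soma_spikes_s: np.ndarray
    post_counts: np.ndarray
    hfs_window_s: tuple[float, float]
    manifest: dict
    probe_t_ms: np.ndarray | None = None
    probe_v: np.ndarray | None = None  # (T, n_probes) mV

    def pct_change(self, t_window: tuple[float, float], baseline_window=None) -> np.ndarray:
        """Per-synapse weight change (%) in a window, relative to pre-HFS baseline."""
        if baseline_window is None:
            baseline_window = self.manifest["baseline_window_s"]
        wb = self._window_mean(baseline_window)
        wf = self._window_mean(t_window)
        return (wf - wb) / wb * 100.0

    def _window_mean(self, window: tuple[float, float]) -> np.ndarray:
        lo, hi = window
        mask = (self.times_s >= lo) & (self.times_s <= hi)
        if not mask.any():
            raise ValueError(f"window {window} outside recorded range")
        return self.w[mask].mean(axis=0)


def _make_cell(spec: ExperimentSpec) -> CellModel:
    return build_cell(mechanisms=spec.mechanism_source, reduced=spec.reduced)


def _spike_rate(cell, pop, weight, duration_ms, dt, noise, isi0, seed, settle_ms=5000.0):
    """Mean somatic rate (Hz) under spontaneous drive at a given weight."""
    pop = replace_weights(pop, weight)
    drive = assemble_drive(
        pop.pathway,
        SpikeTrainSpec(isi0=isi0, noise=noise, t_start=0.0, t_end=duration_ms),
        protocol=None,
        seed=seed,
    )
    res = _run_kernel(
        cell, pop, drive, duration_ms, dt, PlasticityParams(), plasticity_on=False,
        warmup_ms=0.0, rec_every_ms=duration_ms,
    )
    spikes = res["soma_spikes"]
    n = np.count_nonzero(spikes >= settle_ms)
    return n / ((duration_ms - settle_ms) * 1e-3)


def replace_weights(pop: SynapsePopulation, weight: float) -> SynapsePopulation:
    return SynapsePopulation(
        comp=pop.comp,
        pathway=pop.pathway,
        weight=np.full(pop.n, float(weight)),
        path_dist=pop.path_dist,
        tau_rise=pop.tau_rise,
        tau_decay=pop.tau_decay,
        e_rev=pop.e_rev,
    )


def calibrate_baseline_weight(
    cell: CellModel,
    pop: SynapsePopulation,
    params: PlasticityParams,
    dt: float = 0.2,
    noise: float = 0.05,
    isi0: float = 125.0,
    seed: int = 12345,
    duration_s: float = 40.0,
    tol_hz: float = 0.15,
    max_iter: int = 14,
) -> float:
    """Find the uniform baseline weight (µS) giving the target somatic rate.

    The target rate is the fixed point of the homeostatic rule,
    1000/(α·dt) Hz (2 Hz at the defaults), so that at baseline ⟨c⟩ ≈ 1
    and the amplitudes sit at their initial values.  Log-scale bisection
    on the spontaneous-drive firing rate.
    """
    target = 1000.0 / (params.alpha_at(dt) * dt)
    duration_ms = duration_s * 1000.0

    lo, hi = 1e-4, 3e-2  # µS bracket
    r_lo = _spike_rate(cell, pop, lo, duration_ms, dt, noise, isi0, seed)
    r_hi = _spike_rate(cell, pop, hi, duration_ms, dt, noise, isi0, seed)
    grow = 0
    while r_lo > target and grow < 4:
        lo /= 4.0
        r_lo = _spike_rate(cell, pop, lo, duration_ms, dt, noise, isi0, seed)
        grow += 1
    while r_hi < target and grow < 8:
        hi *= 4.0
        r_hi = _spike_rate(cell, pop, hi, duration_ms, dt, noise, isi0, seed)
        grow += 1
    if not (r_lo <= target <= r_hi):
        raise RuntimeError(
            f"cannot bracket target rate {target:.2f} Hz "
            f"(rates {r_lo:.2f}..{r_hi:.2f} Hz at {lo:.2e}..{hi:.2e} µS)"
        )
    w = np.sqrt(lo * hi)
    for _ in range(max_iter):
        w = np.sqrt(lo * hi)
        r = _spike_rate(cell, pop, w, duration_ms, dt, noise, isi0, seed)
        if abs(r - target) <= tol_hz:
            break
        if r < target:
            lo = w
        else:
            hi = w
    return float(w)


def _run_kernel(
    cell: CellModel,
    pop: SynapsePopulation,
    drive: EventStreams,
    duration_ms: float,
    dt: float,
    params: PlasticityParams,
    plasticity_on: bool = True,
    warmup_ms: float = 0.0,
    rec_every_ms: float = 1000.0,
    cell_after: CellModel | None = None,
    t_switch: float = np.inf,
    c_init: float = 0.0,
    probes=None,
    probe_stride: int = 1,
):
    spike_t, spike_syn = drive.flatten()
    start, lst = pop.comp_csr(cell.n)
    n_steps = int(round(duration_ms / dt))
    rec_stride = max(1, int(round(rec_every_ms / dt)))
    probe_idx = (
        np.array([cell.compiled.locate(s, x) for s, x in probes], dtype=np.int64)
        if probes
        else np.empty(0, dtype=np.int64)
    )
    m = cell.mechanisms
    out = _kernel.run_sim(
        parent=cell.compiled.parent,
        g_ax=cell.g_ax,
        cm_abs=cell.cm_abs,
        gl_abs=cell.gl_abs,
        e_l=m.e_leak,
        e_na=m.e_na,
        e_k=m.e_k,
        e_ca=m.e_ca,
        gbar_a=cell.gbar(),
        gbar_b=cell_after.gbar() if cell_after is not None else cell.gbar(),
        t_switch=t_switch if cell_after is not None else np.inf,
        ca_rest=m.ca_rest,
        ca_tau=m.ca_tau,
        ca_fac=cell.ca_fac,
        syn_comp=pop.comp,
        w_init=pop.weight * 1e-3,  # µS -> mS
        tau_r=pop.tau_rise,
        tau_dsyn=pop.tau_decay,
        e_syn=pop.e_rev,
        comp_syn_start=start,
        comp_syn_list=lst,
        spike_t=spike_t,
        spike_syn=spike_syn,
        dt=dt,
        n_steps=n_steps,
        v_init=m.e_leak,
        iinj_comp=0,
        iinj_amp=0.0,
        iinj_t0=0.0,
        iinj_t1=0.0,
        plasticity_on=plasticity_on,
        warmup_ms=warmup_ms,
        ap0=params.a_p0,
        ad0=params.a_d0,
        tau_p=params.tau_p,
        tau_d=params.tau_d,
        tau_c_ms=params.tau_c * 1000.0,
        alpha=params.alpha_at(dt),
        c_floor=params.c_floor,
        v_syn_th=params.v_syn_thresh,
        v_soma_th=params.v_soma_thresh,
        max_change=params.max_change,
        debounce=params.debounce,
        lapse=params.lapse,
        freeze_ap=params.freeze_a_p,
        freeze_ad=params.freeze_a_d,
        c_init=c_init,
        rec_stride=rec_stride,
        probes=probe_idx,
        probe_stride=probe_stride,
    )
    status, fail_t = out[0], out[1]
    if status != 0:
        raise FloatingPointError(f"integration diverged at t = {fail_t:.3f} ms")
    (t_rec, w_rec, c_rec, ap_rec, ad_rec, soma, post_counts, tp_rec, v_probe) = out[2:11]
    return {
        "t_rec": t_rec,
        "w": np.asarray(w_rec, dtype=float) * 1e3,  # mS -> µS
        "c": c_rec,
        "ap": ap_rec,
        "ad": ad_rec,
        "soma_spikes": soma,
        "post_counts": post_counts,
        "probe_t": tp_rec,
        "probe_v": v_probe,
    }


def run_single(spec: ExperimentSpec, run_seed: int, baseline_weight: float) -> SimulationResult:
    """Execute one replicate of an experiment with fully derived randomness."""
    spec.validate()
    cell = _make_cell(spec)
    rng = np.random.default_rng(run_seed)
    pop = attach_synapses(
        cell,
        spec.n_medial,
        spec.n_lateral,
        weight=baseline_weight,
        seed=int(rng.integers(2**31 - 1)),
    )
    protocol = spec.resolve_protocol()
    hfs_t0 = (spec.resolved_warmup_s + spec.baseline_s) * 1000.0
    hfs_span = protocol.span_ms if protocol is not None else 0.0
    duration_ms = hfs_t0 + hfs_span + spec.post_s * 1000.0

    drive = assemble_drive(
        pop.pathway,
        SpikeTrainSpec(isi0=spec.isi0, noise=spec.noise, t_start=0.0, t_end=duration_ms),
        protocol=protocol,
        hfs_t0=hfs_t0,
        lateral_activity_off_at=hfs_t0 if spec.lateral_off_at_hfs else None,
        seed=int(rng.integers(2**31 - 1)),
        merge_window=spec.dt,
    )

    cell_after, t_switch = None, np.inf
    if spec.block_channels:
        layers = spec.block_layers or _ALL_LAYERS
        cell_after = cell.with_block(spec.block_channels, layers, active=False)
        t_switch = hfs_t0

    t0 = time.time()
    res = _run_kernel(
        cell,
        pop,
        drive,
        duration_ms,
        spec.dt,
        spec.plasticity,
        plasticity_on=True,
        warmup_ms=spec.resolved_warmup_s * 1000.0,
        rec_every_ms=spec.record_every_s * 1000.0,
        cell_after=cell_after,
        t_switch=t_switch,
        probes=list(spec.probes) or None,
        probe_stride=max(1, int(round(spec.probe_every_ms / spec.dt))),
    )
    wall = time.time() - t0

    baseline_window = ((hfs_t0 / 1000.0) - min(60.0, spec.baseline_s), hfs_t0 / 1000.0)
    manifest = {
        "package": _pkgname,
        "spec": _spec_dict(spec),
        "run_seed": int(run_seed),
        "baseline_weight_uS": float(baseline_weight),
        "mechanism_source": spec.mechanism_source,
        "n_compartments": cell.n,
        "hfs_t0_s": hfs_t0 / 1000.0,
        "hfs_span_s": hfs_span / 1000.0,
        "baseline_window_s": baseline_window,
        "wall_time_s": wall,
    }
    return SimulationResult(
        times_s=res["t_rec"] / 1000.0,
        w=res["w"],
        pathway=pop.pathway,
        tetanized=drive.tetanized,
        path_dist=pop.path_dist,
        c_avg=res["c"],
        a_p=res["ap"],
        a_d=res["ad"],
        soma_spikes_s=res["soma_spikes"] / 1000.0,
        post_counts=res["post_counts"],
        hfs_window_s=(hfs_t0 / 1000.0, (hfs_t0 + hfs_span) / 1000.0),
        manifest=manifest,
        probe_t_ms=res["probe_t"] if spec.probes else None,
        probe_v=res["probe_v"] if spec.probes else None,
    )


def _spec_dict(spec: ExperimentSpec) -> dict:
    d = asdict(spec)
    if isinstance(d.get("protocol"), dict):
        d["protocol"] = d["protocol"]["name"]
    return d


_calibration_cache: dict[tuple, float] = {}


def run_experiment(spec: ExperimentSpec) -> list[SimulationResult]:
    """Run all replicates of an experiment (one result per run).

    The baseline weight is calibrated once per (mechanism source,
    morphology mode, dt, noise, plasticity α) combination and cached for
    the process lifetime; each replicate then derives its own seeds from
    the experiment seed.
    """
    spec.validate()
    w0 = spec.baseline_weight
    if w0 is None:
        key = (spec.mechanism_source, spec.reduced, spec.dt, spec.noise, spec.isi0,
               spec.plasticity.alpha, spec.plasticity.dt_ref)
        if key not in _calibration_cache:
            cell = _make_cell(spec)
            pop = attach_synapses(cell, spec.n_medial, spec.n_lateral, seed=902101)
            _calibration_cache[key] = calibrate_baseline_weight(
                cell, pop, spec.plasticity, dt=spec.dt, noise=spec.noise, isi0=spec.isi0
            )
        w0 = _calibration_cache[key]

    master = np.random.default_rng(spec.seed)
    run_seeds = master.integers(0, 2**31 - 1, size=spec.n_runs)
    return [run_single(spec, int(s), w0) for s in run_seeds]


def measure_pathway_change(
    results: list[SimulationResult] | SimulationResult,
    pathway: str,
    baseline_window: tuple[float, float] | None = None,
    final_window: tuple[float, float] | None = None,
    tetanized_only: bool | None = None,
) -> tuple[float, float]:
    """Mean ± SD (over runs) of the pathway-average weight change in %.

    Per run, each synapse's change is relative to its own pre-HFS
    baseline and the pathway value is the arithmetic mean over that
    pathway's synapses.  ``tetanized_only`` restricts to (non-)tetanized
    synapses of the pathway.
    """
    if isinstance(results, SimulationResult):
        results = [results]
    per_run = []
    for r in results:
        if final_window is None:
            t_end = r.times_s[-1]
            fw = (t_end - 120.0, t_end)
        else:
            fw = final_window
        mask = r.pathway == pathway
        if tetanized_only is True:
            mask &= r.tetanized
        elif tetanized_only is False:
            mask &= ~r.tetanized
        if not mask.any():
            raise ValueError(f"no synapses selected on pathway {pathway!r}")
        changes = r.pct_change(fw, baseline_window)
        per_run.append(float(changes[mask].mean()))
    arr = np.asarray(per_run)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd


def weight_vs_distance(
    result: SimulationResult,
    baseline_window: tuple[float, float] | None = None,
    final_window: tuple[float, float] | None = None,
):
    """Per-synapse (distance, % change) plus Pearson r within groups.

    Distances are path distances from the soma along the dendrite.  The
    correlation is computed separately for tetanized and non-tetanized
    synapses; degenerate (constant) groups report r = 0 with a flag.
    """
    import pandas as pd

    if final_window is None:
        t_end = result.times_s[-1]
        final_window = (t_end - 120.0, t_end)
    pct = result.pct_change(final_window, baseline_window)
    df = pd.DataFrame(
        {
            "path_dist_um": result.path_dist,
            "pct_change": pct,
            "pathway": result.pathway,
            "tetanized": result.tetanized,
        }
    )
    corrs = {}
    for label, mask in (("tetanized", result.tetanized), ("non_tetanized", ~result.tetanized)):
        if mask.sum() < 2 or np.ptp(pct[mask]) == 0 or np.ptp(result.path_dist[mask]) == 0:
            corrs[label] = {"r": 0.0, "degenerate": True}
        else:
            r, p = stats.pearsonr(result.path_dist[mask], pct[mask])
            corrs[label] = {"r": float(r), "p": float(p), "degenerate": False}
    return df, corrs
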