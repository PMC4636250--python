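"""Cell assembly: morphology + mechanisms -> integrable model, synapse placement.

The :class:`CellModel` binds a compiled morphology to a mechanism
parameter source and exposes per-compartment absolute quantities
(capacitance in µF, conductances in mS) in the layout the simulation
kernel expects.  Channel blocks are conductance multipliers and can be
scheduled mid-run (they take effect at the next integration step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .mechanisms import CHANNELS, MembraneMechanismSet, load_mechanisms
from .morphology import CompiledMorphology, Morphology, default_morphology

__all__ = [
    "CellModel",
    "SynapsePopulation",
    "VoltageTrace",
    "build_cell",
    "attach_synapses",
    "set_channel_block",
    "integrate",
    "double_exp_conductance",
]

#: Synaptic kinetics shared by all perforant-path synapses.
SYN_TAU_RISE = 0.2  # ms
SYN_TAU_DECAY = 2.5  # ms
SYN_E_REV = 0.0  # mV


@dataclass
class CellModel:
    """Discretized granule cell with resolved membrane mechanisms."""

    compiled: CompiledMorphology
    mechanisms: MembraneMechanismSet
    block: np.ndarray = field(default=None)  # (n_channels, N) multipliers

    def __post_init__(self):
        n = self.compiled.n
        areas = self.compiled.area_cm2()
        layers = self.compiled.layer
        self.area = areas
        self.cm_abs = np.array([self.mechanisms.cm[l] for l in layers]) * areas  # µF
        self.gl_abs = np.array([self.mechanisms.g_leak[l] for l in layers]) * areas * 1e3  # mS
        self._gbar0 = self.mechanisms.gbar_matrix(layers) * areas[None, :] * 1e3  # mS
        self.g_ax = self.compiled.axial_g_ms(self.mechanisms.ra)
        if self.block is None:
            self.block = np.ones_like(self._gbar0)
        # shell volume -> mM per µA per ms (calcium influx conversion)
        depth_cm = self.mechanisms.ca_depth * 1e-4
        vol = areas * depth_cm  # cm³
        self.ca_fac = 1e-3 / (2.0 * 96485.0 * vol)

    @property
    def n(self) -> int:
        return self.compiled.n

    def gbar(self) -> np.ndarray:
        """Effective absolute channel conductances (mS) after blocks."""
        return self._gbar0 * self.block

    def with_block(self, channels, layers, active: bool = False) -> "CellModel":
        """Copy of this cell with the named channels (de)activated per layer."""
        for ch in channels:
            if ch not in CHANNELS:
                raise KeyError(f"unknown channel {ch!r}; known: {CHANNELS}")
        block = self.block.copy()
        mask = np.isin(self.compiled.layer, list(layers))
        if not mask.any():
            raise KeyError(f"no compartments in layers {tuple(layers)}")
        for ch in channels:
            block[CHANNELS.index(ch), mask] = 1.0 if active else 0.0
        return CellModel(self.compiled, self.mechanisms, block=block)


def build_cell(
    morphology: Morphology | None = None,
    mechanisms: MembraneMechanismSet | str = "fallback-hh",
    reduced: bool = False,
) -> CellModel:
    """Build an integrable cell from a morphology and a mechanism source."""
    if morphology is None:
        morphology = default_morphology(reduced=reduced)
    morphology.validate()
    if isinstance(mechanisms, str):
        mechanisms = load_mechanisms(mechanisms)
    mechanisms.validate()
    return CellModel(morphology.compile(), mechanisms)


def set_channel_block(cell: CellModel, channels, layers, active: bool = False) -> CellModel:
    """Functional wrapper around :meth:`CellModel.with_block`."""
    return cell.with_block(channels, layers, active=active)


@dataclass
class SynapsePopulation:
    """Perforant-path synapses attached to specific compartments.

    Medial-path synapses sit on middle-molecular-layer segments, lateral
    on outer-molecular-layer segments, spread over both branches.
    Weights are peak conductances in µS.
    """

    comp: np.ndarray  # compartment index per synapse
    pathway: np.ndarray  # 'medial' / 'lateral'
    weight: np.ndarray  # µS
    path_dist: np.ndarray  # µm from soma
    tau_rise: float = SYN_TAU_RISE
    tau_decay: float = SYN_TAU_DECAY
    e_rev: float = SYN_E_REV

    @property
    def n(self) -> int:
        return len(self.comp)

    def validate(self) -> None:
        if np.any(self.weight <= 0):
            raise ValueError("synaptic weights must be strictly positive")

    def comp_csr(self, n_comp: int) -> tuple[np.ndarray, np.ndarray]:
        """CSR mapping compartment -> synapse indices for the kernel."""
        order = np.argsort(self.comp, kind="stable")
        counts = np.bincount(self.comp, minlength=n_comp)
        start = np.concatenate([[0], np.cumsum(counts)])
        return start.astype(np.int64), order.astype(np.int64)


_LAYER_OF_PATHWAY = {"medial": "MML", "lateral": "OML"}


def attach_synapses(
    cell: CellModel,
    n_medial: int = 150,
    n_lateral: int = 150,
    weight: float = 1e-3,
    seed: int = 0,
) -> SynapsePopulation:
    """Place synapses uniformly at random on their pathway's layer segments."""
    if n_medial < 1 or n_lateral < 1:
        raise ValueError("need at least one synapse per pathway")
    rng = np.random.default_rng(seed)
    comps, pathways = [], []
    for pathway, count in (("medial", n_medial), ("lateral", n_lateral)):
        layer = _LAYER_OF_PATHWAY[pathway]
        candidates = cell.compiled.comps_in_layer(layer)
        if len(candidates) == 0:
            raise ValueError(f"no compartments in layer {layer!r} for {pathway} synapses")
        comps.append(rng.choice(candidates, size=count, replace=True))
        pathways += [pathway] * count
    comp = np.concatenate(comps)
    return SynapsePopulation(
        comp=comp.astype(np.int64),
        pathway=np.asarray(pathways),
        weight=np.full(len(comp), float(weight)),
        path_dist=cell.compiled.path_dist[comp],
    )


def double_exp_conductance(t: np.ndarray, w: float, tau_rise=SYN_TAU_RISE, tau_decay=SYN_TAU_DECAY):
    """Analytic difference-of-exponentials conductance, peak-normalized to ``w``."""
    t = np.asarray(t, dtype=float)
    tpk = tau_decay * tau_rise / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    norm = np.exp(-tpk / tau_decay) - np.exp(-tpk / tau_rise)
    g = np.where(t >= 0, (np.exp(-t / tau_decay) - np.exp(-t / tau_rise)) / norm, 0.0)
    return w * g


@dataclass
class VoltageTrace:
    """Membrane potential at one location, uniformly sampled."""

    section: str
    x: float
    times: np.ndarray  # ms
    v: np.ndarray  # mV


def _kernel_args_static(cell: CellModel):
    m = cell.mechanisms
    return dict(
        parent=cell.compiled.parent,
        g_ax=cell.g_ax,
        cm_abs=cell.cm_abs,
        gl_abs=cell.gl_abs,
        e_l=m.e_leak,
        e_na=m.e_na,
        e_k=m.e_k,
        e_ca=m.e_ca,
        ca_rest=m.ca_rest,
        ca_tau=m.ca_tau,
        ca_fac=cell.ca_fac,
    )


def integrate(
    cell: CellModel,
    population: SynapsePopulation | None = None,
    drive=None,
    duration: float = 1000.0,
    dt: float = 0.2,
    probes: list[tuple[str, float]] | None = None,
    iinj: tuple[str, float, float, float, float] | None = None,
    v_init: float | None = None,
    cell_after: CellModel | None = None,
    t_switch: float = np.inf,
) -> list[VoltageTrace]:
    """Integrate the cell with plasticity off and return voltage traces.

    ``drive`` is an :class:`~gcplast.inputs.EventStreams` matching
    ``population`` (or ``None`` for no synaptic input).  ``iinj`` is an
    optional somatic-style current injection
    ``(section, x, amplitude_nA, t0_ms, t1_ms)``.  ``cell_after`` with
    ``t_switch`` swaps the channel conductances mid-run (channel-block
    schedules).  The solution does not depend on the probe list.
    """
    if probes is None:
        probes = [("soma", 0.5)]
    probe_idx = np.array([cell.compiled.locate(s, x) for s, x in probes], dtype=np.int64)

    if population is not None and drive is not None:
        population.validate()
        spike_t, spike_syn = drive.flatten()
        syn_comp = population.comp
        w = population.weight * 1e-3  # µS -> mS
        start, lst = population.comp_csr(cell.n)
        tau_r, tau_ds, e_syn = population.tau_rise, population.tau_decay, population.e_rev
    else:
        spike_t = np.empty(0)
        spike_syn = np.empty(0, dtype=np.int64)
        syn_comp = np.empty(0, dtype=np.int64)
        w = np.empty(0)
        start = np.zeros(cell.n + 1, dtype=np.int64)
        lst = np.empty(0, dtype=np.int64)
        tau_r, tau_ds, e_syn = SYN_TAU_RISE, SYN_TAU_DECAY, SYN_E_REV

    if iinj is not None:
        sec, x, amp_na, t0, t1 = iinj
        iinj_comp = cell.compiled.locate(sec, x)
        iinj_amp = amp_na * 1e-3  # nA -> µA (mS·mV)
    else:
        iinj_comp, iinj_amp, t0, t1 = 0, 0.0, 0.0, 0.0

    gbar_a = cell.gbar()
    gbar_b = cell_after.gbar() if cell_after is not None else gbar_a
    t_sw = t_switch if cell_after is not None else np.inf

    n_steps = int(round(duration / dt))
    out = _kernel.run_sim(
        **_kernel_args_static(cell),
        gbar_a=gbar_a,
        gbar_b=gbar_b,
        t_switch=t_sw,
        syn_comp=syn_comp,
        w_init=w,
        tau_r=tau_r,
        tau_dsyn=tau_ds,
        e_syn=e_syn,
        comp_syn_start=start,
        comp_syn_list=lst,
        spike_t=spike_t,
        spike_syn=spike_syn,
        dt=dt,
        n_steps=n_steps,
        v_init=cell.mechanisms.e_leak if v_init is None else v_init,
        iinj_comp=iinj_comp,
        iinj_amp=iinj_amp,
        iinj_t0=t0,
        iinj_t1=t1,
        plasticity_on=False,
        warmup_ms=0.0,
        ap0=1.0,
        ad0=1.0,
        tau_p=20.0,
        tau_d=70.0,
        tau_c_ms=60e3,
        alpha=2500.0,
        c_floor=1e-3,
        v_syn_th=-37.0,
        v_soma_th=0.0,
        max_change=1.0,
        debounce=5.0,
        lapse=100.0,
        freeze_ap=False,
        freeze_ad=False,
        c_init=0.0,
        rec_stride=max(1, n_steps),
        probes=probe_idx,
        probe_stride=1,
    )
    status, fail_t = out[0], out[1]
    if status != 0:
        raise FloatingPointError(f"integration diverged at t = {fail_t:.3f} ms")
    tp_rec, v_probe = out[9], out[10]
    return [
        VoltageTrace(section=s, x=x, times=tp_rec.copy(), v=v_probe[:, i].copy())
        for i, (s, x) in enumerate(probes)
    ]
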