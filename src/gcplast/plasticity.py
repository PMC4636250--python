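"""Voltage-based nearest-neighbor STDP with fast BCM-like metaplasticity.

The rule has two interacting parts:

**Event-timing STDP.**  For each presynaptic spike only the nearest
postsynaptic events are considered: the latest event at or before the
spike and the earliest event strictly after it (pre-centered
nearest-neighbor scheme).  The postsynaptic "event" is not the somatic
spike but the local dendritic membrane potential at the synapse crossing
a threshold (default -37 mV) from below — so a back-propagating action
potential or sufficiently synchronous synaptic depolarization both
qualify.  With Δt = t_post − t_pre the weight update is multiplicative:

    w <- w * (1 + Δw_p − Δw_d)
    Δw_p = A_p * exp(−Δt/τ_p)   for the following event (Δt > 0)
    Δw_d = A_d * exp(+Δt/τ_d)   for the preceding event (Δt < 0)

**Fast BCM-like homeostasis.**  The amplitudes slide with the recent
average somatic spike count

    ⟨c⟩(t) = (α/τ) ∫ c(t') exp(−(t−t')/τ) dt' ,

(c(t') an indicator of a somatic spike in each integration step), via

    A_p(t) = A_p(0)/⟨c⟩ ,   A_d(t) = A_d(0)·⟨c⟩ ,

so sustained high firing weakens potentiation and strengthens
depression, and vice versa.  The product A_p·A_d is conserved.  α is
tied to the integration step (α·dt constant) so that at a steady firing
rate r the fixed point is ⟨c⟩ = α·dt·r, equal to 1 at the calibrated
2 Hz baseline rate with the default α.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlasticityParams",
    "PlasticityState",
    "detect_events",
    "update_spike_average",
    "update_amplitudes",
    "pair_nearest_neighbor",
    "apply_weight_update",
    "step_plasticity",
    "run_on_streams",
]


@dataclass(frozen=True)
class PlasticityParams:
    """Parameters of the STDP/metaplasticity rule.

    ``alpha`` is referenced to ``dt_ref``; when simulating at a different
    step the effective alpha is rescaled to keep ``alpha * dt`` constant
    (2500 at 0.2 ms == 5000 at 0.1 ms).
    """

    a_p0: float = 0.003  # initial potentiation amplitude (fractional)
    a_d0: float = 0.001  # initial depression amplitude (fractional)
    tau_p: float = 20.0  # potentiation window, ms
    tau_d: float = 70.0  # depression window, ms
    tau_c: float = 60.0  # spike-count integration period, s
    alpha: float = 2500.0  # spike-count scale at dt_ref
    dt_ref: float = 0.2  # ms
    v_syn_thresh: float = -37.0  # local dendritic event threshold, mV
    v_soma_thresh: float = 0.0  # somatic spike threshold, mV
    max_change: float = 1.0  # hard bound: |w - w0| <= max_change * w0
    c_floor: float = 1e-3  # keeps A_p finite before ⟨c⟩ builds up
    debounce: float = 5.0  # ms, min separation of local post events
    lapse_factor: float = 5.0  # pre spike stops waiting after lapse_factor*tau_p
    freeze_a_p: bool = False  # homeostasis-off controls
    freeze_a_d: bool = False

    def __post_init__(self):
        if min(self.tau_p, self.tau_d, self.tau_c) <= 0:
            raise ValueError("time constants must be positive")
        if self.a_p0 <= 0 or self.a_d0 <= 0:
            raise ValueError("amplitudes must be positive")

    def alpha_at(self, dt: float) -> float:
        """Alpha rescaled so that alpha*dt is invariant to the step size."""
        return self.alpha * self.dt_ref / dt

    @property
    def lapse(self) -> float:
        return self.lapse_factor * self.tau_p


def detect_events(
    times: np.ndarray,
    v: np.ndarray,
    threshold: float,
    debounce: float = 5.0,
) -> np.ndarray:
    """Upward threshold crossings of a uniformly sampled voltage trace.

    Crossing times are linearly interpolated between samples.  After a
    crossing no new event is registered for ``debounce`` ms, so a single
    action-potential-width depolarization yields one event.
    """
    v = np.asarray(v, dtype=float)
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage trace contains non-finite samples")
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.flatnonzero(below & above)
    if len(idx) == 0:
        return np.empty(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    crossings = times[idx] + frac * (times[idx + 1] - times[idx])
    events = []
    last = -np.inf
    for t in crossings:
        if t - last >= debounce:
            events.append(t)
            last = t
    return np.asarray(events)


def update_spike_average(
    c_prev: float, spike_in_step: bool | int, dt: float, tau_c: float, alpha: float
) -> float:
    """One step of the exponentially weighted somatic spike count ⟨c⟩.

    Exact one-step form of the defining integral with a per-step spike
    indicator:  ⟨c⟩ <- ⟨c⟩·exp(−dt/τ) + (α/τ)·dt·[spike].

    Parameters are ``dt`` in ms, ``tau_c`` in s, ``alpha`` already scaled
    for this ``dt``.
    """
    tau_ms = tau_c * 1000.0
    c = c_prev * np.exp(-dt / tau_ms)
    if spike_in_step:
        c += (alpha / tau_ms) * dt
    return c


def update_amplitudes(c_avg: float, params: PlasticityParams) -> tuple[float, float]:
    """Slide the STDP amplitudes with the average spike count (BCM part)."""
    c = max(c_avg, params.c_floor)
    a_p = params.a_p0 if params.freeze_a_p else params.a_p0 / c
    a_d = params.a_d0 if params.freeze_a_d else params.a_d0 * c
    return a_p, a_d


def pair_nearest_neighbor(
    pre_time: float, post_events: np.ndarray
) -> tuple[float | None, float | None]:
    """Nearest postsynaptic events around one presynaptic spike.

    Returns ``(dt_before, dt_after)`` with ``dt = t_post - t_pre``:
    ``dt_before <= 0`` from the latest event at or before the spike,
    ``dt_after > 0`` from the earliest event strictly after it; ``None``
    where no such neighbor exists.
    """
    post_events = np.asarray(post_events, dtype=float)
    before = post_events[post_events <= pre_time]
    after = post_events[post_events > pre_time]
    dt_before = float(before[-1] - pre_time) if len(before) else None
    dt_after = float(after[0] - pre_time) if len(after) else None
    return dt_before, dt_after


def stdp_deltas(
    dt_before: float | None,
    dt_after: float | None,
    a_p: float,
    a_d: float,
    tau_p: float,
    tau_d: float,
) -> tuple[float, float]:
    """Window contributions (Δw_p, Δw_d) for one pre-centered pair.

    A coincident event (Δt == 0) contributes to neither window: the
    exponential windows are defined strictly for Δt > 0 and Δt < 0.
    """
    dwp = a_p * np.exp(-dt_after / tau_p) if dt_after is not None and dt_after > 0 else 0.0
    dwd = a_d * np.exp(dt_before / tau_d) if dt_before is not None and dt_before < 0 else 0.0
    return dwp, dwd


def clamp_weight(w: float, w0: float, max_change: float) -> float:
    """Clamp to the hard bounds w0*(1±max_change), keeping w positive."""
    lo = max(w0 * (1.0 - max_change), 1e-12 * w0)
    hi = w0 * (1.0 + max_change)
    return min(max(w, lo), hi)


def apply_weight_update(
    w: float,
    dt_before: float | None,
    dt_after: float | None,
    a_p: float,
    a_d: float,
    tau_p: float,
    tau_d: float,
    w0: float,
    max_change: float = 1.0,
) -> float:
    """Multiplicative weight update for one pre spike's nearest-neighbor pair."""
    if w <= 0:
        raise ValueError("weight must be positive")
    dwp, dwd = stdp_deltas(dt_before, dt_after, a_p, a_d, tau_p, tau_d)
    return clamp_weight(w * (1.0 + dwp - dwd), w0, max_change)


@dataclass
class PlasticityState:
    """Mutable per-synapse and global plasticity state for streamed updates."""

    w: np.ndarray  # current weights
    w0: np.ndarray  # baseline weights (bound reference)
    last_post: np.ndarray  # time of last post event per synapse (-inf if none)
    pending_pre: list[list[float]]  # pre spikes awaiting their next post event
    last_event: np.ndarray  # last accepted post event (debounce), -inf if none
    c_avg: float = 0.0
    a_p: float = 0.0
    a_d: float = 0.0
    t: float = 0.0

    @classmethod
    def init(cls, w0: np.ndarray, params: PlasticityParams) -> "PlasticityState":
        w0 = np.asarray(w0, dtype=float)
        if np.any(w0 <= 0):
            raise ValueError("baseline weights must be positive")
        n = len(w0)
        a_p, a_d = update_amplitudes(0.0, params)
        return cls(
            w=w0.copy(),
            w0=w0.copy(),
            last_post=np.full(n, -np.inf),
            pending_pre=[[] for _ in range(n)],
            last_event=np.full(n, -np.inf),
            a_p=a_p,
            a_d=a_d,
        )


def step_plasticity(
    state: PlasticityState,
    pre_spikes: list[tuple[float, int]],
    post_events: list[tuple[float, int]],
    somatic_spike: bool,
    dt: float,
    params: PlasticityParams,
    enabled: bool = True,
) -> PlasticityState:
    """Advance the plasticity state by one integration step.

    ``pre_spikes`` / ``post_events`` are ``(time, synapse)`` tuples that
    occurred within this step (times must not lie in the future).  The
    spike-count average and the amplitudes are updated every step; each
    pre/post pair's contribution is applied once, at the step in which
    the later member of the pair occurs, with the amplitudes current at
    that step.  ``enabled=False`` runs the bookkeeping (⟨c⟩, amplitudes,
    pairing state) without changing weights — used during warm-up.
    """
    t_next = state.t + dt
    for tt, _ in list(pre_spikes) + list(post_events):
        if tt > t_next + 1e-9:
            raise ValueError(f"event at {tt} ms lies beyond the current step")

    state.c_avg = update_spike_average(
        state.c_avg, somatic_spike, dt, params.tau_c, params.alpha_at(dt)
    )
    state.a_p, state.a_d = update_amplitudes(state.c_avg, params)

    n = len(state.w)
    dwp = np.zeros(n)
    dwd = np.zeros(n)

    # Events are replayed in time order; at exact ties the post event is
    # handled first, which makes a coincident pre/post pair contribute
    # nothing to either window (Δt == 0 semantics).
    events = sorted(
        [(tt, 0, s) for tt, s in post_events] + [(tt, 1, s) for tt, s in pre_spikes]
    )
    for tt, kind, s in events:
        if kind == 0:  # post event
            if tt - state.last_event[s] < params.debounce:
                continue
            state.last_event[s] = tt
            still = []
            for tp in state.pending_pre[s]:
                d = tt - tp
                if d > 0:
                    if d <= params.lapse:
                        dwp[s] += np.exp(-d / params.tau_p)
                    # consumed (or lapsed) either way: tt is its next post
                else:
                    still.append(tp)
            state.pending_pre[s] = still
            state.last_post[s] = tt
        else:  # pre spike
            lp = state.last_post[s]
            if np.isfinite(lp) and lp < tt:
                dwd[s] += np.exp((lp - tt) / params.tau_d)
            state.pending_pre[s].append(tt)
            # drop pre spikes that will never potentiate
            state.pending_pre[s] = [
                tp for tp in state.pending_pre[s] if tt - tp <= params.lapse
            ]

    if enabled:
        factor = 1.0 + state.a_p * dwp - state.a_d * dwd
        w_new = state.w * factor
        lo = np.maximum(state.w0 * (1.0 - params.max_change), 1e-12 * state.w0)
        hi = state.w0 * (1.0 + params.max_change)
        state.w = np.clip(w_new, lo, hi)

    state.t = t_next
    return state


def run_on_streams(
    pre_streams: list[np.ndarray],
    post_streams: list[np.ndarray],
    soma_spikes: np.ndarray,
    duration: float,
    dt: float,
    params: PlasticityParams,
    w0: np.ndarray | None = None,
    warmup: float = 0.0,
    record_every: float | None = None,
):
    """Run the plasticity rule standalone on externally supplied event streams.

    This decouples the rule from the biophysical cell: presynaptic spike
    times, local post-event times, and somatic spike times are given per
    synapse.  Returns a dict with the recorded time series (times, w,
    c_avg, a_p, a_d) and the final state.
    """
    n = len(pre_streams)
    if len(post_streams) != n:
        raise ValueError("pre and post stream counts differ")
    if w0 is None:
        w0 = np.ones(n)
    state = PlasticityState.init(np.asarray(w0, dtype=float), params)

    n_steps = int(round(duration / dt))
    stride = max(1, int(round((record_every or dt) / dt)))
    soma = np.asarray(soma_spikes, dtype=float)

    pre_ptr = [0] * n
    post_ptr = [0] * n
    soma_ptr = 0

    rec_t, rec_w, rec_c, rec_ap, rec_ad = [], [], [], [], []
    for k in range(n_steps):
        t1 = (k + 1) * dt
        pre_ev, post_ev = [], []
        for s in range(n):
            ps = pre_streams[s]
            while pre_ptr[s] < len(ps) and ps[pre_ptr[s]] <= t1:
                pre_ev.append((float(ps[pre_ptr[s]]), s))
                pre_ptr[s] += 1
            qs = post_streams[s]
            while post_ptr[s] < len(qs) and qs[post_ptr[s]] <= t1:
                post_ev.append((float(qs[post_ptr[s]]), s))
                post_ptr[s] += 1
        spike = False
        while soma_ptr < len(soma) and soma[soma_ptr] <= t1:
            spike = True
            soma_ptr += 1
        step_plasticity(
            state, pre_ev, post_ev, spike, dt, params, enabled=t1 > warmup
        )
        if (k + 1) % stride == 0:
            rec_t.append(t1)
            rec_w.append(state.w.copy())
            rec_c.append(state.c_avg)
            rec_ap.append(state.a_p)
            rec_ad.append(state.a_d)

    return {
        "times": np.asarray(rec_t),
        "w": np.asarray(rec_w),
        "c_avg": np.asarray(rec_c),
        "a_p": np.asarray(rec_ap),
        "a_d": np.asarray(rec_ad),
        "state": state,
    }
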