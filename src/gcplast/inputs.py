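"""Afferent drive: spontaneous spike trains and high-frequency stimulation protocols.

Spontaneous presynaptic activity is quasi-periodic.  Each inter-spike
interval is drawn as

    ISI = (1 - noise) * ISI0 + Exponential(mean = noise * ISI0)

so the mean ISI is always ``ISI0`` (8 Hz at the default 125 ms) while the
``noise`` fraction interpolates between a perfectly periodic train
(``noise = 0``) and a homogeneous Poisson train (``noise = 1``).  Every
synapse receives an independent stream; the population is therefore
phase-locked only on average.

Tetanization protocols are deterministic nested burst structures
(pulses within bursts, bursts within trains, repeated trains) delivered
on top of the ongoing spontaneous activity of a random subset of the
medial-path synapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpikeTrainSpec",
    "ProtocolSpec",
    "EventStreams",
    "PROTOCOL_PRESETS",
    "get_protocol",
    "generate_spontaneous",
    "build_protocol",
    "assemble_drive",
    "save_streams",
    "load_streams",
]


@dataclass(frozen=True)
class SpikeTrainSpec:
    """Parameters of one quasi-periodic spontaneous spike train.

    Attributes
    ----------
    isi0 : float
        Mean inter-spike interval in ms (125 ms -> 8 Hz).
    noise : float
        Fraction in [0, 1] of the ISI drawn from an exponential
        distribution; the rest is a fixed dead time.
    seed : int
        Seed for the per-train random stream.
    t_start, t_end : float
        Window (ms) in which spikes are generated.
    """

    isi0: float = 125.0
    noise: float = 0.05
    seed: int = 0
    t_start: float = 0.0
    t_end: float = 1000.0

    def validate(self) -> None:
        if not self.isi0 > 0:
            raise ValueError(f"isi0 must be positive, got {self.isi0}")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError(f"noise must be in [0, 1], got {self.noise}")
        if self.t_end < self.t_start:
            raise ValueError("t_end < t_start")


def generate_spontaneous(spec: SpikeTrainSpec) -> np.ndarray:
    """Generate one spontaneous spike train.

    Returns spike times (ms) in ``[t_start, t_end)``.  The first spike is
    placed one full ISI after ``t_start`` so an ensemble of trains with
    ``noise = 0`` is synchronous rather than all firing at ``t_start``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    span = spec.t_end - spec.t_start
    dead = (1.0 - spec.noise) * spec.isi0
    mean_exp = spec.noise * spec.isi0

    # Draw ISIs in batches until the window is covered.
    n_guess = int(span / spec.isi0 * 1.2) + 16
    chunks: list[np.ndarray] = []
    total = 0.0
    while total < span:
        isi = np.full(n_guess, dead)
        if mean_exp > 0:
            isi = isi + rng.exponential(mean_exp, size=n_guess)
        chunks.append(isi)
        total += float(isi.sum())
    times = spec.t_start + np.cumsum(np.concatenate(chunks))
    return times[times < spec.t_end]


def generate_isis(spec: SpikeTrainSpec, n: int) -> np.ndarray:
    """Draw ``n`` inter-spike intervals directly (for statistics)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    isi = np.full(n, (1.0 - spec.noise) * spec.isi0)
    if spec.noise > 0:
        isi = isi + rng.exponential(spec.noise * spec.isi0, size=n)
    return isi


@dataclass(frozen=True)
class ProtocolSpec:
    """Nested burst/train/repeat timing of a tetanization protocol.

    A protocol is ``n_repeats`` trains separated by
    ``inter_repeat_interval_s``; each train holds ``bursts_per_train``
    bursts at ``inter_burst_freq`` Hz; each burst holds
    ``pulses_per_burst`` pulses at ``intra_burst_freq`` Hz.
    """

    name: str
    pulses_per_burst: int
    intra_burst_freq: float  # Hz
    bursts_per_train: int
    inter_burst_freq: float  # Hz
    n_repeats: int
    inter_repeat_interval_s: float
    tetanized_fraction: float = 1.0
    pathway: str = "medial"

    def validate(self) -> None:
        if min(self.pulses_per_burst, self.bursts_per_train, self.n_repeats) < 1:
            raise ValueError("protocol counts must be >= 1")
        if min(self.intra_burst_freq, self.inter_burst_freq) <= 0:
            raise ValueError("protocol frequencies must be positive")
        if not 0.0 < self.tetanized_fraction <= 1.0:
            raise ValueError("tetanized_fraction must be in (0, 1]")
        burst_dur = (self.pulses_per_burst - 1) * 1000.0 / self.intra_burst_freq
        if self.bursts_per_train > 1 and burst_dur >= 1000.0 / self.inter_burst_freq:
            raise ValueError("bursts overlap: burst duration >= inter-burst interval")
        train_dur = (self.bursts_per_train - 1) * 1000.0 / self.inter_burst_freq + burst_dur
        if self.n_repeats > 1 and train_dur >= self.inter_repeat_interval_s * 1000.0:
            raise ValueError("trains overlap: train duration >= repeat interval")

    @property
    def n_pulses(self) -> int:
        return self.pulses_per_burst * self.bursts_per_train * self.n_repeats

    @property
    def span_ms(self) -> float:
        """Time from the first to the last pulse."""
        return (
            (self.n_repeats - 1) * self.inter_repeat_interval_s * 1000.0
            + (self.bursts_per_train - 1) * 1000.0 / self.inter_burst_freq
            + (self.pulses_per_burst - 1) * 1000.0 / self.intra_burst_freq
        )


#: Named presets: delta-burst (1 Hz inter-burst) and theta-burst (5 Hz
#: inter-burst) patterns at 100 or 400 Hz intra-burst frequency.
PROTOCOL_PRESETS: dict[str, ProtocolSpec] = {
    "400-DBS": ProtocolSpec(
        name="400-DBS",
        pulses_per_burst=10,
        intra_burst_freq=400.0,
        bursts_per_train=5,
        inter_burst_freq=1.0,
        n_repeats=10,
        inter_repeat_interval_s=60.0,
    ),
    "100-TBS": ProtocolSpec(
        name="100-TBS",
        pulses_per_burst=4,
        intra_burst_freq=100.0,
        bursts_per_train=10,
        inter_burst_freq=5.0,
        n_repeats=8,
        inter_repeat_interval_s=10.0,
    ),
    "400-TBS": ProtocolSpec(
        name="400-TBS",
        pulses_per_burst=4,
        intra_burst_freq=400.0,
        bursts_per_train=10,
        inter_burst_freq=5.0,
        n_repeats=8,
        inter_repeat_interval_s=10.0,
    ),
}


def get_protocol(name: str, **overrides) -> ProtocolSpec:
    """Look up a protocol preset, optionally overriding fields."""
    try:
        preset = PROTOCOL_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; available: {sorted(PROTOCOL_PRESETS)}"
        ) from None
    return replace(preset, **overrides) if overrides else preset


def build_protocol(spec: ProtocolSpec, t0: float = 0.0) -> np.ndarray:
    """Return the deterministic pulse times (ms) of a protocol starting at ``t0``."""
    spec.validate()
    pulse = np.arange(spec.pulses_per_burst) * 1000.0 / spec.intra_burst_freq
    burst = np.arange(spec.bursts_per_train) * 1000.0 / spec.inter_burst_freq
    repeat = np.arange(spec.n_repeats) * spec.inter_repeat_interval_s * 1000.0
    times = t0 + repeat[:, None, None] + burst[None, :, None] + pulse[None, None, :]
    return times.ravel()


@dataclass
class EventStreams:
    """Per-synapse presynaptic spike times plus tetanization flags."""

    times: list[np.ndarray]
    tetanized: np.ndarray  # bool per synapse
    pathway: np.ndarray = field(default=None)  # 'medial'/'lateral' per synapse

    @property
    def n_synapses(self) -> int:
        return len(self.times)

    def validate(self) -> None:
        for i, t in enumerate(self.times):
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"stream {i} is not strictly increasing")

    def flatten(self) -> tuple[np.ndarray, np.ndarray]:
        """All spikes merged across synapses, sorted by time.

        Returns ``(times, synapse_ids)`` ready for the simulation kernel.
        """
        if not self.times:
            return np.empty(0), np.empty(0, dtype=np.int64)
        all_t = np.concatenate(self.times)
        all_s = np.concatenate(
            [np.full(len(t), i, dtype=np.int64) for i, t in enumerate(self.times)]
        )
        order = np.argsort(all_t, kind="stable")
        return all_t[order], all_s[order]


def _merge_dedupe(a: np.ndarray, b: np.ndarray, window: float) -> np.ndarray:
    """Merge two sorted spike trains; collapse spikes closer than ``window``.

    A synapse cannot release twice within one integration step, so a
    spontaneous spike landing on top of a protocol pulse counts once.
    """
    merged = np.sort(np.concatenate([a, b]))
    if len(merged) < 2:
        return merged
    keep = np.empty(len(merged), dtype=bool)
    keep[0] = True
    last = merged[0]
    for i in range(1, len(merged)):
        if merged[i] - last >= window:
            keep[i] = True
            last = merged[i]
        else:
            keep[i] = False
    return merged[keep]


def assemble_drive(
    pathway: np.ndarray,
    spont_spec: SpikeTrainSpec,
    protocol: ProtocolSpec | None = None,
    hfs_t0: float = 0.0,
    lateral_activity_off_at: float | None = None,
    seed: int = 0,
    merge_window: float = 0.2,
) -> EventStreams:
    """Build the full presynaptic drive for a synapse population.

    Parameters
    ----------
    pathway : array of str
        'medial' or 'lateral' per synapse (defines placement of the tetanus
        and the lateral-off control).
    spont_spec : SpikeTrainSpec
        Template for the spontaneous trains; each synapse gets an
        independent seed derived from ``seed``.
    protocol : ProtocolSpec or None
        Tetanization protocol; its pulses are added to a random subset of
        ``tetanized_fraction`` of the target pathway's synapses.
    hfs_t0 : float
        Onset (ms) of the first protocol pulse.
    lateral_activity_off_at : float or None
        If set, all lateral-path spikes at or after this time are removed
        (control demonstrating that heterosynaptic depression needs
        ongoing lateral activity).
    merge_window : float
        Spikes closer than this (ms) at one synapse are collapsed.
    """
    pathway = np.asarray(pathway)
    n = len(pathway)
    rng = np.random.default_rng(seed)
    # Independent spawn per synapse keeps streams independent of n and of
    # each other while remaining reproducible under the run seed.
    seeds = rng.integers(0, 2**31 - 1, size=n)

    times = []
    for i in range(n):
        s = replace(spont_spec, seed=int(seeds[i]))
        times.append(generate_spontaneous(s))

    tetanized = np.zeros(n, dtype=bool)
    if protocol is not None:
        protocol.validate()
        import warnings

        if protocol.pathway == "lateral":
            warnings.warn(
                "protocol targets the lateral pathway; the standard "
                "experiments tetanize the medial path",
                stacklevel=2,
            )
        target = np.flatnonzero(pathway == protocol.pathway)
        if len(target) == 0:
            raise ValueError(f"no synapses on pathway {protocol.pathway!r}")
        n_tet = int(round(protocol.tetanized_fraction * len(target)))
        n_tet = max(1, n_tet)
        chosen = rng.choice(target, size=n_tet, replace=False)
        tetanized[chosen] = True
        pulses = build_protocol(protocol, t0=hfs_t0)
        for i in chosen:
            times[i] = _merge_dedupe(times[i], pulses, merge_window)

    if lateral_activity_off_at is not None:
        for i in np.flatnonzero(pathway == "lateral"):
            times[i] = times[i][times[i] < lateral_activity_off_at]

    return EventStreams(times=times, tetanized=tetanized, pathway=pathway)


def save_streams(path, streams: EventStreams) -> None:
    """Write spike streams as two-column text: synapse_id, time_ms."""
    t, s = streams.flatten()
    with open(path, "w") as fh:
        fh.write("# synapse_id time_ms\n")
        for si, ti in zip(s, t):
            fh.write(f"{si} {ti:.6f}\n")


def load_streams(path, n_synapses: int | None = None) -> EventStreams:
    """Read spike streams written by :func:`save_streams`."""
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        n = n_synapses or 0
        return EventStreams(
            times=[np.empty(0) for _ in range(n)],
            tetanized=np.zeros(n, dtype=bool),
        )
    ids = data[:, 0].astype(int)
    t = data[:, 1]
    n = n_synapses if n_synapses is not None else ids.max() + 1
    times = [np.sort(t[ids == i]) for i in range(n)]
    return EventStreams(times=times, tetanized=np.zeros(n, dtype=bool))
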