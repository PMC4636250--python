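"""Membrane mechanism parameter sources.

Channel kinetics are code; channel *densities* and passive parameters
are data, keyed by a named source in a small registry:

``"fallback-hh"``
    The default, self-contained set: Hodgkin-Huxley-style Na and fast
    delayed-rectifier K everywhere plus a generic high-threshold Ca
    channel and a Ca-gated SK channel in the dendrites.  Tuned to give a
    stable rest near -70 mV, somatic spiking with refractoriness at
    400 Hz drive, and actively supported back-propagation that carries
    the action potential above the -37 mV plasticity threshold out to
    the distal dendrites.  Intended for qualitative work and tests.

``"modeldb-51781"``
    A transcription of the densities of the published dentate granule
    cell model with nine voltage-gated channels (Na, fast/slow delayed
    rectifier K, A-type K, T/N/L-type Ca, SK, BK).  Quantitative claims
    made with this source are conditional on the fidelity of the
    transcription.

Any channel can be zeroed per layer without rebuilding the cell (used
for the channel-block experiments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .morphology import LAYERS

__all__ = ["CHANNELS", "CA_CHANNELS", "MembraneMechanismSet", "load_mechanisms", "available_sources"]

#: Channel roster, in kernel row order.
CHANNELS = ("na", "kdrf", "kdrs", "ka", "cat", "can", "cal", "sk", "bk")
#: Channels whose current feeds the intracellular Ca pool.
CA_CHANNELS = ("cat", "can", "cal")


@dataclass(frozen=True)
class MembraneMechanismSet:
    """Densities (S/cm²) per layer per channel plus passive parameters."""

    source: str
    densities: dict  # layer -> channel -> S/cm²
    cm: dict  # layer -> µF/cm²
    g_leak: dict  # layer -> S/cm²
    ra: float  # Ω·cm
    e_leak: float  # mV
    e_na: float
    e_k: float
    e_ca: float
    ca_rest: float  # mM
    ca_tau: float  # ms
    ca_depth: float  # µm, shell depth converting I_Ca to d[Ca]/dt

    def validate(self) -> None:
        for layer in LAYERS:
            if layer not in self.densities:
                raise ValueError(f"source {self.source!r} missing layer {layer!r}")
            for ch in self.densities[layer]:
                if ch not in CHANNELS:
                    raise ValueError(f"unknown channel {ch!r} in layer {layer!r}")
            if layer not in self.cm or layer not in self.g_leak:
                raise ValueError(f"missing passive parameters for layer {layer!r}")
        if self.ra <= 0:
            raise ValueError("axial resistivity must be positive")

    def density(self, layer: str, channel: str) -> float:
        return float(self.densities[layer].get(channel, 0.0))

    def gbar_matrix(self, layers: np.ndarray) -> np.ndarray:
        """Density matrix (S/cm²), shape (n_channels, n_compartments)."""
        g = np.zeros((len(CHANNELS), len(layers)))
        for ci, ch in enumerate(CHANNELS):
            for i, layer in enumerate(layers):
                g[ci, i] = self.density(layer, ch)
        return g


_SOURCE_FILES = {
    "fallback-hh": "mechanisms_fallback_hh.json",
    "modeldb-51781": "mechanisms_modeldb_51781.json",
}


def available_sources() -> list[str]:
    return sorted(_SOURCE_FILES)


def load_mechanisms(source: str = "fallback-hh") -> MembraneMechanismSet:
    """Load a mechanism parameter source from the bundled registry."""
    if source not in _SOURCE_FILES:
        raise KeyError(f"unknown mechanism source {source!r}; available: {available_sources()}")
    path = resources.files("gcplast.data").joinpath(_SOURCE_FILES[source])
    raw = json.loads(path.read_text())
    mset = MembraneMechanismSet(
        source=source,
        densities=raw["densities"],
        cm=raw["cm"],
        g_leak=raw["g_leak"],
        ra=raw["ra"],
        e_leak=raw["e_leak"],
        e_na=raw["e_na"],
        e_k=raw["e_k"],
        e_ca=raw["e_ca"],
        ca_rest=raw["ca_rest"],
        ca_tau=raw["ca_tau"],
        ca_depth=raw["ca_depth"],
    )
    mset.validate()
    return mset
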