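"""Reduced granule-cell morphology and its compartmental discretization.

The cell is a soma with two symmetric dendritic branches, each branch a
chain of four sections tagged by layer: granule cell layer (GCL, 50 µm),
then inner, middle and outer molecular layer sections (IML/MML/OML,
150 µm each).  Medial perforant-path synapses terminate on the MML
sections, lateral perforant-path synapses on the OML sections.

Two discretizations are supported: the full mode (soma 1 segment, GCL
5 each, IML/MML/OML 19 each -> 125 compartments) and a reduced mode with
one segment per section (9 compartments) used for parameter scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Section", "Morphology", "CompiledMorphology", "default_morphology", "LAYERS"]

LAYERS = ("soma", "GCL", "IML", "MML", "OML")


@dataclass(frozen=True)
class Section:
    name: str
    length: float  # µm
    diam: float  # µm
    nseg: int
    parent: str | None
    layer: str


@dataclass(frozen=True)
class Morphology:
    sections: tuple[Section, ...]

    def validate(self) -> None:
        names = [s.name for s in self.sections]
        if len(set(names)) != len(names):
            raise ValueError("duplicate section names")
        by_layer: dict[str, int] = {}
        for s in self.sections:
            if s.layer not in LAYERS:
                raise ValueError(f"unknown layer tag {s.layer!r}")
            if s.length <= 0 or s.diam <= 0 or s.nseg < 1:
                raise ValueError(f"non-positive geometry in section {s.name!r}")
            if s.parent is not None and s.parent not in names:
                raise ValueError(f"unknown parent {s.parent!r}")
            by_layer[s.layer] = by_layer.get(s.layer, 0) + 1
        expected = {"soma": 1, "GCL": 2, "IML": 2, "MML": 2, "OML": 2}
        if by_layer != expected:
            raise ValueError(f"section count per layer {by_layer} != {expected}")

    @property
    def n_compartments(self) -> int:
        return sum(s.nseg for s in self.sections)

    def compile(self) -> "CompiledMorphology":
        """Flatten into per-compartment arrays with parent links.

        Compartments are ordered soma first, then each branch root-to-tip,
        so every compartment's parent has a smaller index (the ordering
        required by the tree solver).
        """
        self.validate()
        secs = {s.name: s for s in self.sections}
        order: list[Section] = []
        soma = next(s for s in self.sections if s.layer == "soma")
        order.append(soma)
        # walk children depth-first
        def children(name):
            return [s for s in self.sections if s.parent == name]

        stack = children(soma.name)[::-1]
        while stack:
            s = stack.pop()
            order.append(s)
            stack.extend(children(s.name)[::-1])
        if len(order) != len(self.sections):
            raise ValueError("sections do not form a single tree rooted at the soma")

        n = self.n_compartments
        parent = np.full(n, -1, dtype=np.int64)
        sec_index = np.zeros(n, dtype=np.int64)
        seg_pos = np.zeros(n)  # normalized position of segment center in section
        length = np.zeros(n)  # µm, segment length
        diam = np.zeros(n)
        layer = np.empty(n, dtype=object)
        path_dist = np.zeros(n)  # µm along the path from the soma center

        first_comp: dict[str, int] = {}
        last_comp: dict[str, int] = {}
        idx = 0
        for si, s in enumerate(order):
            lseg = s.length / s.nseg
            for j in range(s.nseg):
                sec_index[idx] = si
                seg_pos[idx] = (j + 0.5) / s.nseg
                length[idx] = lseg
                diam[idx] = s.diam
                layer[idx] = s.layer
                if j == 0:
                    if s.parent is None:
                        parent[idx] = -1
                        path_dist[idx] = 0.0
                    else:
                        p = last_comp[s.parent]
                        parent[idx] = p
                        # distance from parent segment center to this center
                        path_dist[idx] = path_dist[p] + length[p] / 2 + lseg / 2
                    first_comp[s.name] = idx
                else:
                    parent[idx] = idx - 1
                    path_dist[idx] = path_dist[idx - 1] + lseg
                last_comp[s.name] = idx
                idx += 1

        return CompiledMorphology(
            morphology=self,
            section_order=tuple(s.name for s in order),
            parent=parent,
            sec_index=sec_index,
            seg_pos=seg_pos,
            length=length,
            diam=diam,
            layer=np.asarray(layer),
            path_dist=path_dist,
        )


@dataclass(frozen=True)
class CompiledMorphology:
    """Per-compartment arrays derived from a :class:`Morphology`."""

    morphology: Morphology
    section_order: tuple[str, ...]
    parent: np.ndarray
    sec_index: np.ndarray
    seg_pos: np.ndarray
    length: np.ndarray  # µm
    diam: np.ndarray  # µm
    layer: np.ndarray
    path_dist: np.ndarray  # µm

    @property
    def n(self) -> int:
        return len(self.parent)

    def area_cm2(self) -> np.ndarray:
        """Lateral cylinder area per compartment in cm²."""
        return np.pi * (self.diam * 1e-4) * (self.length * 1e-4)

    def axial_g_ms(self, ra: float) -> np.ndarray:
        """Axial conductance (mS) between each compartment and its parent.

        ``ra`` is the axial resistivity in Ω·cm.  Half-segment resistances
        on either side of the junction are summed.
        """
        n = self.n
        g = np.zeros(n)
        xarea = np.pi * (self.diam * 1e-4) ** 2 / 4.0  # cm²
        half = ra * (self.length * 1e-4 / 2.0) / xarea  # Ω
        for i in range(n):
            p = self.parent[i]
            if p < 0:
                continue
            g[i] = 1e3 / (half[i] + half[p])  # S -> mS
        return g

    def comps_in_layer(self, layer: str) -> np.ndarray:
        return np.flatnonzero(self.layer == layer)

    def locate(self, section: str, x: float) -> int:
        """Compartment index of normalized position ``x`` in ``section``."""
        if section not in self.section_order:
            raise KeyError(f"unknown section {section!r}")
        si = self.section_order.index(section)
        comps = np.flatnonzero(self.sec_index == si)
        j = min(int(x * len(comps)), len(comps) - 1)
        return int(comps[j])


def default_morphology(reduced: bool = False) -> Morphology:
    """The standard two-branch granule-cell morphology.

    ``reduced=True`` gives one segment per section (9 compartments);
    otherwise the full 125-compartment discretization.
    """
    def nseg(full):
        return 1 if reduced else full

    secs = [Section("soma", 16.8, 16.8, 1, None, "soma")]
    for b in (1, 2):
        secs += [
            Section(f"gcl{b}", 50.0, 3.0, nseg(5), "soma", "GCL"),
            Section(f"iml{b}", 150.0, 3.0, nseg(19), f"gcl{b}", "IML"),
            Section(f"mml{b}", 150.0, 3.0, nseg(19), f"iml{b}", "MML"),
            Section(f"oml{b}", 150.0, 3.0, nseg(19), f"mml{b}", "OML"),
        ]
    m = Morphology(tuple(secs))
    m.validate()
    return m
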