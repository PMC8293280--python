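"""Stylized SNc dopaminergic neuron morphologies.

Generates populations of reduced but realistic morphologies (large soma,
a handful of branching dendritic trunks, and an axon-start / axon-initial-
segment / axon chain) standing in for reconstructed cells, reads and writes
them as standard 7-column SWC, and discretizes sections into odd numbers of
iso-potential compartments with the d_lambda rule (compartment length at most
a fraction ``d_lambda`` of the AC length constant at a reference frequency).

Section kinds and channel regions: the soma, dendrites and the axon-start
section carry the full channel complement ("soma_dend" density region); the
AIS and axon carry only Na, KDR and leak.  SWC has no axon-start/AIS/axon
distinction, so a JSON sidecar written next to each SWC file records the
section kind of every node.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Optional

import numpy as np

__all__ = [
    "Section",
    "Morphology",
    "PassiveSpec",
    "DiscretizationPolicy",
    "MorphologyTemplate",
    "CompartmentSet",
    "generate_population",
    "lambda_f",
    "discretize",
    "read_swc",
    "write_swc",
]

SECTION_KINDS = ("soma", "dendrite", "axon_start", "AIS", "axon")

# Density region per section kind (axon_start carries the full complement).
KIND_TO_REGION = {
    "soma": "soma_dend",
    "dendrite": "soma_dend",
    "axon_start": "soma_dend",
    "AIS": "AIS",
    "axon": "axon",
}

_SWC_TYPE = {"soma": 1, "axon_start": 2, "AIS": 2, "axon": 2, "dendrite": 3}


@dataclass
class Section:
    """One unbranched cylindrical section of the morphology."""

    kind: str
    length: float  # um
    diameter: float  # um
    parent: int  # index into Morphology.sections, -1 for the root soma

    def __post_init__(self) -> None:
        if self.kind not in SECTION_KINDS:
            raise ValueError(f"unknown section kind {self.kind!r}")
        if self.length <= 0 or self.diameter <= 0:
            raise ValueError("section length and diameter must be positive")

    @property
    def area(self) -> float:
        """Lateral membrane area pi*d*L (um^2); for the soma (L = d) this
        equals the surface of the equivalent sphere."""
        return math.pi * self.diameter * self.length


@dataclass
class Morphology:
    """A connected, acyclic tree of sections; section 0 is the soma."""

    sections: List[Section]
    id: str = "morph"

    def __post_init__(self) -> None:
        if not self.sections or self.sections[0].kind != "soma":
            raise ValueError("section 0 must be the soma")
        if sum(1 for s in self.sections if s.kind == "soma") != 1:
            raise ValueError("exactly one soma section required")
        for i, s in enumerate(self.sections):
            if i == 0:
                if s.parent != -1:
                    raise ValueError("soma must be the root (parent -1)")
            elif not 0 <= s.parent < i:
                raise ValueError(f"section {i} parent must precede it in the list")
            if s.kind == "AIS" and self.sections[s.parent].kind != "axon_start":
                raise ValueError("AIS must attach to axon_start")
            if s.kind == "axon" and self.sections[s.parent].kind not in ("AIS", "axon"):
                raise ValueError("axon must attach to AIS (or continue an axon)")

    @property
    def total_area(self) -> float:
        return sum(s.area for s in self.sections)


@dataclass(frozen=True)
class PassiveSpec:
    """Passive cable properties (defaults as used throughout the model)."""

    axial_resistivity: float = 150.0  # Ohm cm
    specific_capacitance: float = 0.75  # uF/cm^2
    specific_membrane_resistance: float = 100_000.0  # Ohm cm^2
    e_leak: float = -50.0  # mV

    def __post_init__(self) -> None:
        if min(self.axial_resistivity, self.specific_capacitance,
               self.specific_membrane_resistance) <= 0:
            raise ValueError("passive parameters must be positive")


@dataclass(frozen=True)
class DiscretizationPolicy:
    """d_lambda rule parameters: max compartment length as a fraction of the
    AC length constant at ``frequency``."""

    d_lambda: float = 0.1
    frequency: float = 100.0  # Hz

    def __post_init__(self) -> None:
        if not 0 < self.d_lambda <= 1:
            raise ValueError("d_lambda must lie in (0, 1]")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")


@dataclass(frozen=True)
class MorphologyTemplate:
    """Ranges (uniform draws) and fixed dimensions for the generator.

    Defaults give a large soma (>25 um, the electrophysiological
    identification criterion for SNc DA neurons), 3-6 tapering binary-branched
    dendritic trunks and a short axon-start -> AIS -> axon chain.
    """

    soma_diameter: tuple = (25.0, 30.0)
    n_dendrites: tuple = (3, 6)  # inclusive integer range
    trunk_length: tuple = (120.0, 260.0)
    trunk_diameter: tuple = (1.5, 3.0)
    branch_depth: int = 2  # binary branch orders beyond the trunk
    branch_prob: float = 0.7  # probability a branch point actually branches
    child_length_ratio: tuple = (0.5, 0.9)
    child_diameter_ratio: float = 0.7
    axon_start_length: float = 20.0
    axon_start_diameter: float = 1.8
    ais_length: float = 30.0
    ais_diameter: float = 1.2
    axon_length: float = 300.0
    axon_diameter: float = 1.0


def generate_population(
    n: int, seed: int, template: Optional[MorphologyTemplate] = None
) -> List[Morphology]:
    """Generate ``n`` stylized morphologies, deterministically for a seed."""
    if n <= 0:
        raise ValueError("population size must be at least 1")
    tpl = template or MorphologyTemplate()
    rng = np.random.default_rng(seed)
    return [_generate_one(rng, tpl, f"syn{idx:03d}") for idx in range(n)]


def _generate_one(rng: np.random.Generator, tpl: MorphologyTemplate, mid: str) -> Morphology:
    secs: List[Section] = []
    soma_d = rng.uniform(*tpl.soma_diameter)
    secs.append(Section("soma", soma_d, soma_d, -1))
    secs.append(Section("axon_start", tpl.axon_start_length, tpl.axon_start_diameter, 0))
    secs.append(Section("AIS", tpl.ais_length, tpl.ais_diameter, 1))
    secs.append(Section("axon", tpl.axon_length, tpl.axon_diameter, 2))

    def grow(parent_idx: int, length: float, diam: float, depth: int) -> None:
        secs.append(Section("dendrite", length, diam, parent_idx))
        idx = len(secs) - 1
        # binary branching (0 or 2 children) keeps SWC chains unambiguous
        if depth < tpl.branch_depth and rng.random() < tpl.branch_prob:
            for _ in range(2):
                ratio = rng.uniform(*tpl.child_length_ratio)
                grow(idx, length * ratio, diam * tpl.child_diameter_ratio, depth + 1)

    n_dend = int(rng.integers(tpl.n_dendrites[0], tpl.n_dendrites[1] + 1))
    for _ in range(n_dend):
        grow(0, rng.uniform(*tpl.trunk_length), rng.uniform(*tpl.trunk_diameter), 0)
    return Morphology(sections=secs, id=mid)


def lambda_f(diameter: float, passive: PassiveSpec, frequency: float) -> float:
    """AC length constant (um) at ``frequency`` (Hz) for a cable of the given
    diameter (um): ``0.5 * sqrt(d / (pi * f * Ra * Cm))`` in consistent units.
    """
    if diameter <= 0 or frequency <= 0:
        raise ValueError("diameter and frequency must be positive")
    d_cm = diameter * 1e-4
    cm_f = passive.specific_capacitance * 1e-6  # F/cm^2
    lam_cm = 0.5 * math.sqrt(
        d_cm / (math.pi * frequency * passive.axial_resistivity * cm_f)
    )
    return lam_cm * 1e4  # um


@dataclass
class CompartmentSet:
    """Flat compartment arrays produced by :func:`discretize`.

    ``parent[i]`` indexes the compartment the i-th compartment couples to
    (-1 for the root); parents always precede children, so the arrays are in
    valid elimination order for a branched (Hines-style) tridiagonal solve.
    """

    section_index: np.ndarray  # int, per compartment
    kind: np.ndarray  # str section kind per compartment
    region: np.ndarray  # str density region per compartment
    length: np.ndarray  # um
    diameter: np.ndarray  # um
    area: np.ndarray  # um^2
    parent: np.ndarray  # int compartment index, -1 for root
    morphology_id: str = ""

    @property
    def n(self) -> int:
        return self.length.size

    def section_compartments(self, sec_idx: int) -> np.ndarray:
        return np.flatnonzero(self.section_index == sec_idx)

    def middle_of(self, kind: str) -> int:
        """Index of the middle compartment of the first section of a kind."""
        for si in np.unique(self.section_index):
            comps = self.section_compartments(si)
            if self.kind[comps[0]] == kind:
                return int(comps[comps.size // 2])
        raise KeyError(f"no section of kind {kind!r}")


def discretize(
    m: Morphology,
    policy: DiscretizationPolicy | None = None,
    passive: PassiveSpec | None = None,
) -> CompartmentSet:
    """Split every section into the smallest odd number of equal compartments
    with length at most ``d_lambda * lambda_f`` (the d_lambda rule).

    Child sections attach to the middle compartment of the soma, or to the
    distal compartment of any other parent section.  Compartment areas sum
    exactly to the cylindrical section areas.
    """
    policy = policy or DiscretizationPolicy()
    passive = passive or PassiveSpec()
    sec_idx, kinds, regions, lengths, diams, parents = [], [], [], [], [], []
    first_comp: List[int] = []  # first compartment index per section
    last_comp: List[int] = []
    mid_comp: List[int] = []
    for si, sec in enumerate(m.sections):
        lam = lambda_f(sec.diameter, passive, policy.frequency)
        nseg = max(1, math.ceil(sec.length / (policy.d_lambda * lam)))
        if nseg % 2 == 0:
            nseg += 1
        if si == 0:
            parent_comp = -1
        else:
            psec = sec.parent
            parent_comp = mid_comp[psec] if m.sections[psec].kind == "soma" else last_comp[psec]
        start = len(lengths)
        for k in range(nseg):
            sec_idx.append(si)
            kinds.append(sec.kind)
            regions.append(KIND_TO_REGION[sec.kind])
            lengths.append(sec.length / nseg)
            diams.append(sec.diameter)
            parents.append(parent_comp if k == 0 else start + k - 1)
        first_comp.append(start)
        last_comp.append(start + nseg - 1)
        mid_comp.append(start + nseg // 2)
    length = np.array(lengths)
    diam = np.array(diams)
    return CompartmentSet(
        section_index=np.array(sec_idx, dtype=np.int64),
        kind=np.array(kinds, dtype=object),
        region=np.array(regions, dtype=object),
        length=length,
        diameter=diam,
        area=np.pi * diam * length,
        parent=np.array(parents, dtype=np.int64),
        morphology_id=m.id,
    )


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def _fibonacci_direction(k: int) -> np.ndarray:
    """Deterministic, well-spread unit vector for the k-th section (spherical
    Fibonacci lattice); used only to synthesize 3D coordinates for SWC."""
    golden = (1 + 5**0.5) / 2
    i = k + 1
    z = 1 - 2 * (i % 97) / 97.0
    theta = 2 * math.pi * i / golden
    r = math.sqrt(max(0.0, 1 - z * z))
    return np.array([r * math.cos(theta), r * math.sin(theta), z])


def write_swc(m: Morphology, path) -> None:
    """Write a morphology as 7-column SWC plus a region-annotation sidecar
    (``<path>.regions.json``) mapping node ids to section kinds."""
    path = Path(path)
    lines = ["# id type x y z radius parent", ]
    # node 1: soma (single point, radius d/2)
    endpoints = {0: np.zeros(3)}
    node_of_section = {0: 1}
    sidecar = {"1": {"kind": "soma", "section": 0}}
    lines.append(f"1 1 0.0 0.0 0.0 {m.sections[0].diameter / 2:.6f} -1")
    nid = 1
    for si, sec in enumerate(m.sections):
        if si == 0:
            continue
        nid += 1
        start = endpoints[sec.parent]
        end = start + _fibonacci_direction(si) * sec.length
        endpoints[si] = end
        node_of_section[si] = nid
        lines.append(
            f"{nid} {_SWC_TYPE[sec.kind]} {end[0]:.6f} {end[1]:.6f} {end[2]:.6f} "
            f"{sec.diameter / 2:.6f} {node_of_section[sec.parent]}"
        )
        sidecar[str(nid)] = {"kind": sec.kind, "section": si}
    path.write_text("\n".join(lines) + "\n")
    Path(str(path) + ".regions.json").write_text(json.dumps({"id": m.id, "nodes": sidecar}, indent=1))


def read_swc(path) -> Morphology:
    """Read a 7-column SWC file (with optional region sidecar) back into a
    :class:`Morphology`.

    Without a sidecar, axon-family nodes (SWC type 2) are assigned kinds
    axon_start/AIS/axon in path order, and unbranched runs of same-kind nodes
    are merged into single sections.  Malformed rows or orphan nodes raise
    ``ValueError`` naming the offending line/node.
    """
    path = Path(path)
    sidecar_path = Path(str(path) + ".regions.json")
    sidecar = None
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    nodes = {}
    order = []
    for ln, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC at line {ln}: expected 7 columns")
        try:
            nid = int(parts[0]); ntype = int(parts[1])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
            radius = float(parts[5]); parent = int(parts[6])
        except ValueError as exc:
            raise ValueError(f"malformed SWC at line {ln}: {exc}") from None
        nodes[nid] = dict(type=ntype, xyz=xyz, radius=radius, parent=parent)
        order.append(nid)
    if not order:
        raise ValueError("empty SWC file")
    for nid in order:
        p = nodes[nid]["parent"]
        if p != -1 and p not in nodes:
            raise ValueError(f"orphan SWC node {nid}: parent {p} not defined")

    roots = [nid for nid in order if nodes[nid]["parent"] == -1]
    if len(roots) != 1 or nodes[roots[0]]["type"] != 1:
        raise ValueError("SWC must have exactly one root soma node")
    soma_id = roots[0]
    children: dict = {nid: [] for nid in order}
    for nid in order:
        p = nodes[nid]["parent"]
        if p != -1:
            children[p].append(nid)

    def node_kind(nid: int) -> str:
        if sidecar is not None:
            return sidecar["nodes"][str(nid)]["kind"]
        t = nodes[nid]["type"]
        return {1: "soma", 3: "dendrite"}.get(t, "axon")

    soma_d = 2 * nodes[soma_id]["radius"]
    sections = [Section("soma", soma_d, soma_d, -1)]
    sec_of_node = {soma_id: 0}
    axon_seen = 0

    def walk(nid: int, parent_sec: int) -> None:
        nonlocal axon_seen
        # one section per maximal unbranched chain of dendrite nodes; axon-
        # family nodes are never merged so the start/AIS/axon split survives
        chain = [nid]
        while (
            sidecar is None
            and node_kind(nid) == "dendrite"
            and len(children[chain[-1]]) == 1
            and node_kind(children[chain[-1]][0]) == "dendrite"
        ):
            chain.append(children[chain[-1]][0])
        length = 0.0
        prev = nodes[nid]["parent"]
        for cn in chain:
            length += float(np.linalg.norm(nodes[cn]["xyz"] - nodes[prev]["xyz"]))
            prev = cn
        kind = node_kind(nid)
        if sidecar is None and kind == "axon":
            kind = ("axon_start", "AIS", "axon")[min(axon_seen, 2)]
            axon_seen += 1
        sections.append(Section(kind, max(length, 1e-9), 2 * nodes[chain[-1]]["radius"], parent_sec))
        sec = len(sections) - 1
        for cn in chain:
            sec_of_node[cn] = sec
        for child in children[chain[-1]]:
            walk(child, sec)

    for child in children[soma_id]:
        walk(child, 0)
    mid = sidecar["id"] if sidecar is not None else path.stem
    return Morphology(sections=sections, id=mid)
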