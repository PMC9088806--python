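"""Assembly of the pneumatic system graph.

supply -> bell jar -> main 2" line (lead + one node per 2.2 m patient
module) -> per-patient 1/2" inspiratory limb (switch valve, one-way valve)
-> lung -> expiratory limb (one-way valve, switch valve, PEEP threshold) ->
atmosphere.  Expiratory lines are independent per patient and never rejoin
the main line (cross-contamination barrier); inspiration/expiration may
never share an element, so a single three-way valve is forbidden and the
two switch valves operate in counterphase.

Layouts: a single linear row, an L-shaped row (fluidically identical to
linear), a T (a tee splits the inflow into two limbs), or a clover (a
central cross splits it into three orthogonal limbs).  Each limb is a
``lead_length`` m run to the row of beds plus 2.2 m per patient module
(200 cm pipe + 20 cm T-element).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .components import BellJarSpec, PatientSpec, PipeSpec, SupplySpec, ValveSpec
from .design_calc import pipe_volume_per_m

__all__ = [
    "ConfigurationError",
    "LayoutSpec",
    "Node",
    "Edge",
    "SystemModel",
    "Scenario",
    "build_system",
    "patient_distances",
    "validate_system",
    "LAYOUT_LIMBS",
]

#: number of distribution limbs radiating from the bell jar, per layout shape
LAYOUT_LIMBS = {"linear": 1, "L": 1, "T": 2, "clover": 3}

ATMOSPHERE = "atmosphere"
BJS_NODE = "bjs"


class ConfigurationError(ValueError):
    """The requested system assembly is inconsistent."""


@dataclass(frozen=True)
class LayoutSpec:
    """Geometric arrangement of the distribution line.

    ``patients_per_limb`` assigns patients to limbs in order; the default is
    ten patients on one linear limb.  Each module is 2.2 m (200 cm pipe +
    20 cm T-element); each limb starts with a ``lead_length`` m run from the
    bell jar to its row of beds.
    """

    shape: str = "linear"
    patients_per_limb: tuple[int, ...] = (10,)
    module_length: float = 2.2
    lead_length: float = 3.0
    max_patients: int = 10
    pipe_internal_diameter: float = 50.8  # mm

    def __post_init__(self) -> None:
        if self.shape not in LAYOUT_LIMBS:
            raise ConfigurationError(
                f"unknown layout shape {self.shape!r}; expected one of {sorted(LAYOUT_LIMBS)}"
            )
        object.__setattr__(self, "patients_per_limb", tuple(self.patients_per_limb))
        n_limbs = LAYOUT_LIMBS[self.shape]
        if len(self.patients_per_limb) != n_limbs:
            raise ConfigurationError(
                f"{self.shape!r} layout has {n_limbs} limb(s); got counts "
                f"{self.patients_per_limb}"
            )
        if any(n < 0 for n in self.patients_per_limb):
            raise ConfigurationError("patients_per_limb counts must be nonnegative")
        if self.total_patients > self.max_patients:
            raise ConfigurationError(
                f"{self.total_patients} patients exceed layout capacity {self.max_patients}"
            )
        if not self.module_length > 0 or not self.lead_length >= 0:
            raise ConfigurationError("module_length must be > 0 and lead_length >= 0")

    @property
    def total_patients(self) -> int:
        return sum(self.patients_per_limb)

    def limb_length(self, limb: int) -> float:
        """Total main-line length of one limb (m): lead + n modules."""
        return self.lead_length + self.patients_per_limb[limb] * self.module_length


@dataclass(frozen=True)
class Node:
    """A pneumatic node with a stored-gas volume (L); kind is one of
    bjs/lead/module/lung/limb/atmosphere."""

    name: str
    kind: str
    volume_l: float = 0.0


@dataclass(frozen=True)
class Edge:
    """A flow element between two nodes.

    kinds: ``pipe`` (friction run, carries a PipeSpec), ``switch_valve``
    (controller-driven Kv element), ``one_way`` (check valve), ``peep``
    (expiratory threshold), ``relief`` (water-seal safety vent).
    """

    kind: str
    src: str
    dst: str
    pipe: PipeSpec | None = None
    valve: ValveSpec | None = None
    patient: int | None = None
    limb: str | None = None  # "insp" / "exp" for patient limbs


@dataclass(frozen=True)
class SystemModel:
    """The assembled pneumatic network."""

    nodes: tuple[Node, ...]
    edges: tuple[Edge, ...]
    patient_attachments: tuple[str, ...]  # patient k -> main-line node name
    supply_attachment: str
    layout: LayoutSpec

    def node(self, name: str) -> Node:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def n_patients(self) -> int:
        return len(self.patient_attachments)

    def main_line_volume(self) -> float:
        """Dead volume (L) of the main-line pipe runs."""
        return sum(n.volume_l for n in self.nodes if n.kind in ("lead", "module"))


@dataclass(frozen=True)
class Scenario:
    """A complete, runnable description of one ventilation episode."""

    system: SystemModel
    patients: tuple[PatientSpec, ...]
    bjs: BellJarSpec
    supply: SupplySpec
    controllers: tuple  # one PCVConfig per patient (see controllers module)
    duration: float
    synchronous_start: bool = True
    limb_valve: ValveSpec = ValveSpec()
    #: close each inspiratory valve once the breath's delivered volume
    #: reaches the patient's tidal target (volume-guarantee cut-off)
    volume_cutoff: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "patients", tuple(self.patients))
        object.__setattr__(self, "controllers", tuple(self.controllers))
        if len(self.controllers) != len(self.patients):
            raise ConfigurationError(
                f"{len(self.controllers)} controllers for {len(self.patients)} patients"
            )
        if self.duration < 0:
            raise ConfigurationError("duration must be nonnegative")


def build_system(
    layout: LayoutSpec,
    patients: Sequence[PatientSpec],
    bjs: BellJarSpec = BellJarSpec(),
    supply: SupplySpec = SupplySpec(),
) -> SystemModel:
    """Assemble the pneumatic graph for a layout and patient list.

    Patients are attached limb by limb in list order; patient #1 sits nearest
    the bell jar and #N farthest.  The returned model carries each patient's
    distance from the bell jar in its ``PatientSpec``.
    """
    patients = list(patients)
    if len(patients) != layout.total_patients:
        raise ConfigurationError(
            f"layout expects {layout.total_patients} patients, got {len(patients)}"
        )

    vol_per_m = pipe_volume_per_m(layout.pipe_internal_diameter)
    nodes: list[Node] = [Node(BJS_NODE, "bjs", volume_l=bjs.dead_volume)]
    edges: list[Edge] = [Edge("relief", BJS_NODE, ATMOSPHERE)]
    attachments: list[str] = []

    k = 0  # global patient index
    for limb_idx, n_limb in enumerate(layout.patients_per_limb):
        lead_name = f"limb{limb_idx}/lead"
        lead_pipe = PipeSpec(length=layout.lead_length, internal_diameter=layout.pipe_internal_diameter)
        nodes.append(Node(lead_name, "lead", volume_l=layout.lead_length * vol_per_m))
        edges.append(Edge("pipe", BJS_NODE, lead_name, pipe=lead_pipe))
        upstream = lead_name
        for j in range(n_limb):
            mod_name = f"limb{limb_idx}/module{j}"
            mod_pipe = PipeSpec(length=layout.module_length, internal_diameter=layout.pipe_internal_diameter)
            nodes.append(Node(mod_name, "module", volume_l=layout.module_length * vol_per_m))
            edges.append(Edge("pipe", upstream, mod_name, pipe=mod_pipe))

            distance = layout.lead_length + (j + 1) * layout.module_length
            patients[k] = replace(patients[k], distance_from_bjs=distance)

            wye = f"patient{k}/insp_wye"
            lung = f"patient{k}/lung"
            exp_mid = f"patient{k}/exp_mid"
            peep_in = f"patient{k}/peep_in"
            nodes += [Node(wye, "limb"), Node(lung, "lung"), Node(exp_mid, "limb"), Node(peep_in, "limb")]
            edges += [
                Edge("switch_valve", mod_name, wye, valve=ValveSpec(), patient=k, limb="insp"),
                Edge("one_way", wye, lung, valve=ValveSpec(one_way=True), patient=k, limb="insp"),
                Edge("one_way", lung, exp_mid, valve=ValveSpec(one_way=True), patient=k, limb="exp"),
                Edge("switch_valve", exp_mid, peep_in, valve=ValveSpec(), patient=k, limb="exp"),
                Edge("peep", peep_in, ATMOSPHERE, patient=k, limb="exp"),
            ]
            attachments.append(mod_name)
            upstream = mod_name
            k += 1

    nodes.append(Node(ATMOSPHERE, "atmosphere"))
    model = SystemModel(
        nodes=tuple(nodes),
        edges=tuple(edges),
        patient_attachments=tuple(attachments),
        supply_attachment=BJS_NODE,
        layout=layout,
    )
    violations = validate_system(model)
    if violations:
        raise ConfigurationError("built system is invalid: " + "; ".join(violations))
    return model


def patients_with_distances(system: SystemModel, patients: Sequence[PatientSpec]) -> tuple[PatientSpec, ...]:
    """Return the patient list annotated with distances from the bell jar."""
    dists = patient_distances(system)
    return tuple(replace(p, distance_from_bjs=d) for p, d in zip(patients, dists))


def patient_distances(system: SystemModel) -> list[float]:
    """Per-patient main-line distance (m) from the bell jar, in patient order.

    Nonnegative and nondecreasing along each limb.
    """
    dists: list[float] = []
    lay = system.layout
    k = 0
    for n_limb in lay.patients_per_limb:
        for j in range(n_limb):
            dists.append(lay.lead_length + (j + 1) * lay.module_length)
            k += 1
    return dists


def validate_system(system: SystemModel) -> list[str]:
    """Check the topological invariants; an empty list means valid.

    Violations (returned as data, not raised): missing relief vent on the
    bell jar; an element shared between a patient's inspiratory and
    expiratory limbs (a three-way switch is forbidden); missing one-way
    valves at the limb ends; expiratory paths of distinct patients sharing
    any element; expiratory lines rejoining the main line; disconnected
    graph.
    """
    violations: list[str] = []
    names = {n.name for n in system.nodes}
    main_nodes = {n.name for n in system.nodes if n.kind in ("bjs", "lead", "module")}

    if not any(e.kind == "relief" and e.src == BJS_NODE for e in system.edges):
        violations.append("no relief vent on the bell-jar node")

    n_pat = system.n_patients
    for k in range(n_pat):
        insp = [e for e in system.edges if e.patient == k and e.limb == "insp"]
        exp = [e for e in system.edges if e.patient == k and e.limb == "exp"]
        shared = {(e.src, e.dst) for e in insp} & {(e.src, e.dst) for e in exp}
        if shared:
            violations.append(f"patient {k}: common inspiratory/expiratory element {sorted(shared)}")
        if not any(e.kind == "one_way" for e in insp):
            violations.append(f"patient {k}: inspiratory limb lacks a one-way valve")
        if not any(e.kind == "one_way" for e in exp):
            violations.append(f"patient {k}: expiratory limb lacks a one-way valve")
        # expiratory line must discharge to atmosphere, never into the main line
        for e in exp:
            if e.dst in main_nodes:
                violations.append(f"patient {k}: expiratory line rejoins the main line at {e.dst}")

    # expiratory subgraphs of distinct patients must be disjoint
    exp_nodes: dict[int, set[str]] = {}
    for k in range(n_pat):
        nodes_k = set()
        for e in system.edges:
            if e.patient == k and e.limb == "exp":
                nodes_k.update((e.src, e.dst))
        exp_nodes[k] = nodes_k - {ATMOSPHERE} - {f"patient{k}/lung"}
    for a in range(n_pat):
        for b in range(a + 1, n_pat):
            common = exp_nodes[a] & exp_nodes[b]
            if common:
                violations.append(f"patients {a} and {b} share expiratory elements {sorted(common)}")

    # connectivity: every node reachable from the bell jar, edges undirected
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(names)
    g.add_edges_from((e.src, e.dst) for e in system.edges)
    if BJS_NODE in names:
        reachable = nx.node_connected_component(g, BJS_NODE)
        unreachable = names - reachable
        if unreachable:
            violations.append(f"nodes unreachable from the bell jar: {sorted(unreachable)}")
    else:
        violations.append("no bell-jar node")

    return violations
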