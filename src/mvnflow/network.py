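"""Vascular network graph model, file I/O, validation and cortical layers.

A microvascular network is a labeled graph: nodes carry 3D coordinates
(x, y, z in micrometres, z = depth below the pial surface, increasing
downward) and a boundary flag marking in/outflow candidates; edges are
vessels with a diameter, a length (which may exceed the straight-line
endpoint distance because real vessels are tortuous) and an anatomical
type label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

VESSEL_TYPES = (
    "pial_artery",
    "penetrating_arteriole",
    "arteriole_offshoot",
    "capillary",
    "venule_offshoot",
    "ascending_venule",
    "pial_vein",
)

ARTERIAL_TYPES = frozenset({"pial_artery", "penetrating_arteriole", "arteriole_offshoot"})
VENOUS_TYPES = frozenset({"venule_offshoot", "ascending_venule", "pial_vein"})

#: Tolerance (relative) when checking vessel length >= endpoint chord.
_CHORD_TOL = 1e-6


class SchemaError(ValueError):
    """Raised when an input table violates the network file schema."""


@dataclass(frozen=True)
class NetworkNode:
    """A bifurcation point or vessel endpoint.

    z is depth below the pia in µm (>= 0 at the surface); ``is_boundary``
    marks nodes where blood may enter or leave the simulation domain.
    """

    id: str
    x: float
    y: float
    z: float
    is_boundary: bool = False


@dataclass(frozen=True)
class Vessel:
    """A vessel segment between two nodes.

    ``length`` is the tortuous centerline length in µm and may exceed the
    Euclidean endpoint distance. ``centerline_z`` optionally samples depth
    along the centerline for depth averaging.
    """

    id: str
    node_a: str
    node_b: str
    diameter: float
    length: float
    type: str
    centerline_z: tuple[float, ...] = ()

    @property
    def cross_section(self) -> float:
        """Cross-sectional area πD²/4 in µm²."""
        return math.pi * self.diameter**2 / 4.0

    @property
    def volume(self) -> float:
        """Cylindrical volume in µm³ (1 µm³ = 1 fl)."""
        return self.cross_section * self.length


@dataclass(frozen=True)
class CorticalLayer:
    label: str
    depth_min: float
    depth_max: float  # exclusive; inf for the deepest bin

    def contains(self, depth: float) -> bool:
        return self.depth_min <= depth < self.depth_max


#: Cortical layer bins in µm of depth below the pia. The deepest bin (L6,
#: including the corpus callosum) is open-ended beyond 800 µm.
CORTICAL_LAYERS = (
    CorticalLayer("L1", 0.0, 200.0),
    CorticalLayer("L2_3", 200.0, 400.0),
    CorticalLayer("L4", 400.0, 600.0),
    CorticalLayer("L5", 600.0, 800.0),
    CorticalLayer("L6", 800.0, math.inf),
)

LAYER_LABELS = tuple(l.label for l in CORTICAL_LAYERS)


@dataclass
class ValidationReport:
    """Accumulated invariant violations; empty iff the network is valid."""

    violations: list[tuple[str, str]] = field(default_factory=list)

    def add(self, element_id: str, message: str) -> None:
        self.violations.append((element_id, message))

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        if self.ok:
            return "ValidationReport: OK"
        lines = [f"  {eid}: {msg}" for eid, msg in self.violations]
        return "ValidationReport: {} violation(s)\n{}".format(len(self.violations), "\n".join(lines))


class VascularNetwork:
    """A validated vascular graph of nodes and vessels.

    Multi-edges (two distinct vessels joining the same node pair, e.g. a
    capillary loop) are allowed, so the underlying container is a
    :class:`networkx.MultiGraph` keyed by vessel id.
    """

    def __init__(
        self,
        nodes: Iterable[NetworkNode],
        vessels: Iterable[Vessel],
        name: str = "network",
        validate: bool = True,
    ):
        self.name = name
        self.nodes: dict[str, NetworkNode] = {}
        for n in nodes:
            if n.id in self.nodes:
                raise SchemaError(f"duplicate node id {n.id!r}")
            self.nodes[n.id] = n
        self.vessels: dict[str, Vessel] = {}
        for v in vessels:
            if v.id in self.vessels:
                raise SchemaError(f"duplicate vessel id {v.id!r}")
            for end in (v.node_a, v.node_b):
                if end not in self.nodes:
                    raise SchemaError(f"vessel {v.id!r} references missing node {end!r}")
            self.vessels[v.id] = v
        if validate:
            report = validate_network(self)
            if not report.ok:
                raise SchemaError(f"invalid network:\n{report}")

    # -- graph views ---------------------------------------------------
    def graph(self) -> nx.MultiGraph:
        g = nx.MultiGraph()
        for n in self.nodes.values():
            g.add_node(n.id, node=n)
        for v in self.vessels.values():
            g.add_edge(v.node_a, v.node_b, key=v.id, vessel=v)
        return g

    def boundary_nodes(self) -> list[NetworkNode]:
        return [n for n in self.nodes.values() if n.is_boundary]

    def incident_vessels(self, node_id: str) -> list[Vessel]:
        return [v for v in self.vessels.values() if node_id in (v.node_a, v.node_b)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VascularNetwork):
            return NotImplemented
        return self.nodes == other.nodes and self.vessels == other.vessels

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<VascularNetwork {self.name!r}: {len(self.nodes)} nodes, {len(self.vessels)} vessels>"


# ----------------------------------------------------------------------
# Validation


def validate_network(net: VascularNetwork) -> ValidationReport:
    """Check all structural invariants; report rather than raise.

    Checks: positive diameters/lengths, distinct endpoints, known type
    labels, non-negative depths, length >= endpoint chord, and that every
    vessel is reachable from at least one boundary node (perfusability).
    """
    report = ValidationReport()
    for n in net.nodes.values():
        if n.z < 0:
            report.add(n.id, f"negative depth z={n.z}")
    for v in net.vessels.values():
        if v.diameter <= 0:
            report.add(v.id, f"non-positive diameter {v.diameter}")
        if v.length <= 0:
            report.add(v.id, f"non-positive length {v.length}")
        if v.node_a == v.node_b:
            report.add(v.id, "self-loop (node_a == node_b)")
        if v.type not in VESSEL_TYPES:
            report.add(v.id, f"unknown vessel type {v.type!r}")
        a, b = net.nodes.get(v.node_a), net.nodes.get(v.node_b)
        if a is not None and b is not None and v.length > 0:
            chord = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
            if v.length < chord * (1.0 - _CHORD_TOL) - 1e-9:
                report.add(v.id, f"length {v.length:.6g} µm shorter than endpoint chord {chord:.6g} µm")

    # perfused-component connectivity: every vessel reachable from a boundary
    boundary = [n.id for n in net.boundary_nodes()]
    if not boundary:
        report.add("<network>", "no boundary nodes flagged")
    elif net.vessels:
        g = net.graph()
        reached: set[str] = set()
        for b in boundary:
            if b in g:
                reached |= nx.node_connected_component(g, b)
        for v in net.vessels.values():
            if v.node_a not in reached and v.node_b not in reached:
                report.add(v.id, "unreachable from any boundary node")
    return report


# ----------------------------------------------------------------------
# Depth and layers


def vessel_depth(v: Vessel, net: VascularNetwork) -> float:
    """Mean cortical depth of a vessel in µm.

    Uses the centerline z-samples when present (tortuous-coordinate
    average), otherwise the mean of the two endpoint depths.
    """
    if v.centerline_z:
        return sum(v.centerline_z) / len(v.centerline_z)
    a, b = net.nodes[v.node_a], net.nodes[v.node_b]
    return 0.5 * (a.z + b.z)


def layer_of_depth(depth: float) -> CorticalLayer:
    if depth < 0:
        raise ValueError(f"negative depth {depth}")
    for layer in CORTICAL_LAYERS:
        if layer.contains(depth):
            return layer
    raise ValueError(f"depth {depth} outside all layer bins")  # pragma: no cover


def assign_layers(net: VascularNetwork) -> dict[str, CorticalLayer]:
    """Map every vessel id to its cortical layer by mean depth."""
    return {vid: layer_of_depth(vessel_depth(v, net)) for vid, v in net.vessels.items()}


# ----------------------------------------------------------------------
# File I/O (CSV pair and single-file JSON)


def _parse_centerline(raw: object) -> tuple[float, ...]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return ()
    s = str(raw).strip()
    if not s:
        return ()
    return tuple(float(t) for t in s.split(";"))


def load_network(node_table_path: str | Path, vessel_table_path: str | Path, name: str | None = None) -> VascularNetwork:
    """Load a network from the nodes.csv / vessels.csv table pair."""
    ndf = pd.read_csv(node_table_path, dtype={"node_id": str}, float_precision="round_trip")
    vdf = pd.read_csv(
        vessel_table_path, dtype={"vessel_id": str, "node_a": str, "node_b": str}, float_precision="round_trip"
    )
    required_n = {"node_id", "x_um", "y_um", "z_um", "is_boundary"}
    required_v = {"vessel_id", "node_a", "node_b", "diameter_um", "length_um", "type"}
    if missing := required_n - set(ndf.columns):
        raise SchemaError(f"nodes table missing columns {sorted(missing)}")
    if missing := required_v - set(vdf.columns):
        raise SchemaError(f"vessels table missing columns {sorted(missing)}")
    nodes = [
        NetworkNode(str(r.node_id), float(r.x_um), float(r.y_um), float(r.z_um), bool(int(r.is_boundary)))
        for r in ndf.itertuples()
    ]
    has_cl = "centerline_z" in vdf.columns
    vessels = []
    for r in vdf.itertuples():
        if r.diameter_um <= 0 or r.length_um <= 0:
            raise ValueError(f"vessel {r.vessel_id!r}: non-positive diameter or length")
        vessels.append(
            Vessel(
                str(r.vessel_id),
                str(r.node_a),
                str(r.node_b),
                float(r.diameter_um),
                float(r.length_um),
                str(r.type),
                _parse_centerline(getattr(r, "centerline_z", None) if has_cl else None),
            )
        )
    if name is None:
        name = Path(node_table_path).resolve().parent.name
    return VascularNetwork(nodes, vessels, name=name)


def save_network(net: VascularNetwork, node_table_path: str | Path, vessel_table_path: str | Path) -> None:
    """Write the nodes.csv / vessels.csv pair (UTF-8, header row)."""
    ndf = pd.DataFrame(
        {
            "node_id": [n.id for n in net.nodes.values()],
            "x_um": [repr(n.x) for n in net.nodes.values()],
            "y_um": [repr(n.y) for n in net.nodes.values()],
            "z_um": [repr(n.z) for n in net.nodes.values()],
            "is_boundary": [int(n.is_boundary) for n in net.nodes.values()],
        }
    )
    vdf = pd.DataFrame(
        {
            "vessel_id": [v.id for v in net.vessels.values()],
            "node_a": [v.node_a for v in net.vessels.values()],
            "node_b": [v.node_b for v in net.vessels.values()],
            "diameter_um": [repr(v.diameter) for v in net.vessels.values()],
            "length_um": [repr(v.length) for v in net.vessels.values()],
            "type": [v.type for v in net.vessels.values()],
            "centerline_z": [";".join(repr(z) for z in v.centerline_z) for v in net.vessels.values()],
        }
    )
    ndf.to_csv(node_table_path, index=False)
    vdf.to_csv(vessel_table_path, index=False)


def to_json(net: VascularNetwork, path: str | Path) -> None:
    """Single-file JSON form mirroring the CSV schema."""
    payload = {
        "name": net.name,
        "units": "um",
        "nodes": [
            {"node_id": n.id, "x_um": n.x, "y_um": n.y, "z_um": n.z, "is_boundary": int(n.is_boundary)}
            for n in net.nodes.values()
        ],
        "vessels": [
            {
                "vessel_id": v.id,
                "node_a": v.node_a,
                "node_b": v.node_b,
                "diameter_um": v.diameter,
                "length_um": v.length,
                "type": v.type,
                "centerline_z": list(v.centerline_z),
            }
            for v in net.vessels.values()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def from_json(path: str | Path) -> VascularNetwork:
    payload = json.loads(Path(path).read_text())
    nodes = [
        NetworkNode(str(d["node_id"]), float(d["x_um"]), float(d["y_um"]), float(d["z_um"]), bool(d["is_boundary"]))
        for d in payload["nodes"]
    ]
    vessels = [
        Vessel(
            str(d["vessel_id"]),
            str(d["node_a"]),
            str(d["node_b"]),
            float(d["diameter_um"]),
            float(d["length_um"]),
            str(d["type"]),
            tuple(float(z) for z in d.get("centerline_z", ())),
        )
        for d in payload["vessels"]
    ]
    return VascularNetwork(nodes, vessels, name=payload.get("name", "network"))
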