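"""Synthetic cortical microvascular network generator.

Generates networks with the statistical structure of reconstructed
mouse-cortex microvascular networks: a capillary bed holding ~96% of the
total vascular length with ~4 µm diameters, penetrating arteriole and
ascending venule trunks spanning a ~1,000 µm cortical depth, at least one
PCV-like venule whose offshoots drain only the deepest layers, and
explicit in/outflow boundary nodes at the pial surface and at cut trunk
ends below it.

Construction: capillaries form stacked, jittered honeycomb lattice planes
(degree-3 dominant, so the drainage topology is bifurcation-dominated),
linked vertically by a random subset of inter-plane edges. Trunks are
vertical chains with one offshoot per crossed plane connecting to the
nearest free lattice node. All randomness flows from a single seed, so a
given (params, seed) pair reproduces the network exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable

import networkx as nx
import numpy as np

from .network import (
    CORTICAL_LAYERS,
    NetworkNode,
    VascularNetwork,
    Vessel,
    assign_layers,
    vessel_depth,
)


class GeneratorConfigurationError(ValueError):
    """Generator parameters cannot yield a perfusable network."""


@dataclass(frozen=True)
class DiameterSpec:
    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        return np.clip(rng.normal(self.mean, self.sd, size=n), self.lo, self.hi)


@dataclass
class GeneratorParams:
    """Tunable structure of the synthetic column.

    The defaults target the MVN1-like statistics: ~2,000 vessels at desk
    scale, capillary length share ~96%, capillary diameters 4 ± 0.5 µm,
    max depth 1,000 µm. ``hex_cells`` sets the honeycomb lattice size per
    plane (hexagon rows = columns); ``n_planes`` the number of capillary
    planes stacked over the depth.
    """

    max_depth_um: float = 1000.0
    hex_cells: int = 7
    n_planes: int = 10
    hex_edge_um: float = 60.0
    vertical_link_fraction: float = 0.30
    jitter_frac: float = 0.12
    tortuosity_mean: float = 1.25
    tortuosity_sd: float = 0.10
    trifurcation_fraction: float = 0.0

    n_arterioles: int = 3
    n_ascending_venules: int = 2
    n_pcv: int = 1
    pcv_min_offshoot_depth_um: float = 600.0
    trunk_taper: float = 0.30  # fractional diameter loss at max depth

    capillary_d: DiameterSpec = field(default_factory=lambda: DiameterSpec(4.0, 0.5, 2.8, 6.0))
    arteriole_offshoot_d: DiameterSpec = field(default_factory=lambda: DiameterSpec(8.0, 0.8, 6.0, 11.0))
    venule_offshoot_d: DiameterSpec = field(default_factory=lambda: DiameterSpec(10.0, 1.0, 7.5, 14.0))
    arteriole_trunk_d: DiameterSpec = field(default_factory=lambda: DiameterSpec(15.0, 1.5, 12.0, 19.0))
    venule_trunk_d: DiameterSpec = field(default_factory=lambda: DiameterSpec(20.0, 2.0, 16.0, 26.0))
    pcv_trunk_d: DiameterSpec = field(default_factory=lambda: DiameterSpec(45.0, 5.0, 35.0, 60.0))
    pial_artery_d: float = 25.0
    pial_vein_d: float = 35.0

    target_capillary_length_fraction: float = 0.96

    def validate(self) -> None:
        if self.n_arterioles <= 0:
            raise GeneratorConfigurationError("need at least one penetrating arteriole to perfuse the network")
        if self.n_ascending_venules + self.n_pcv <= 0:
            raise GeneratorConfigurationError("need at least one venule trunk to drain the network")
        if self.hex_cells < 2 or self.n_planes < 2:
            raise GeneratorConfigurationError("lattice too small (hex_cells >= 2, n_planes >= 2)")
        if not 0.0 < self.target_capillary_length_fraction < 1.0:
            raise GeneratorConfigurationError("capillary length fraction must be in (0, 1)")
        if self.hex_edge_um <= 0 or self.vertical_link_fraction < 0:
            raise GeneratorConfigurationError("spacing must be positive and link fraction non-negative")


MVN1_LIKE = GeneratorParams()


def _spread_positions(rng: np.random.Generator, n: int, xlim: tuple[float, float], ylim: tuple[float, float],
                      existing: list[tuple[float, float]], n_candidates: int = 40) -> list[tuple[float, float]]:
    """Greedy best-candidate sampling for well-separated trunk positions."""
    placed = list(existing)
    out = []
    for _ in range(n):
        cand = np.column_stack(
            [rng.uniform(xlim[0], xlim[1], n_candidates), rng.uniform(ylim[0], ylim[1], n_candidates)]
        )
        if placed:
            pts = np.array(placed)
            d = np.sqrt(((cand[:, None, :] - pts[None, :, :]) ** 2).sum(-1)).min(axis=1)
            best = cand[int(np.argmax(d))]
        else:
            best = cand[0]
        pos = (float(best[0]), float(best[1]))
        placed.append(pos)
        out.append(pos)
    return out


def generate_network(params: GeneratorParams = MVN1_LIKE, seed: int = 0, name: str | None = None) -> VascularNetwork:
    """Build a synthetic cortical-column network (deterministic per seed)."""
    params.validate()
    rng = np.random.default_rng(seed)
    nodes: dict[str, NetworkNode] = {}
    vessels: list[Vessel] = []
    vid_counter = 0

    def add_node(nid: str, x: float, y: float, z: float, boundary: bool = False) -> str:
        nodes[nid] = NetworkNode(nid, x, y, z, boundary)
        return nid

    def add_vessel(a: str, b: str, d: float, vtype: str, tortuosity: float | None = None) -> str:
        nonlocal vid_counter
        na, nb = nodes[a], nodes[b]
        chord = math.dist((na.x, na.y, na.z), (nb.x, nb.y, nb.z))
        if tortuosity is None:
            tortuosity = float(np.clip(rng.normal(params.tortuosity_mean, params.tortuosity_sd), 1.02, 1.6))
        vid = f"v{vid_counter:05d}"
        vid_counter += 1
        vessels.append(Vessel(vid, a, b, float(d), chord * tortuosity, vtype))
        return vid

    # ---- capillary lattice planes ------------------------------------
    m = params.hex_cells
    hexg = nx.hexagonal_lattice_graph(m, m)
    pos = nx.get_node_attributes(hexg, "pos")
    lattice_nodes = sorted(hexg.nodes())
    lattice_edges = sorted(tuple(sorted(e)) for e in hexg.edges())
    scale = params.hex_edge_um
    dz = params.max_depth_um / params.n_planes
    jitter = params.jitter_frac * scale

    def cap_id(p: int, key: tuple) -> str:
        return f"c{p}_{key[0]}_{key[1]}"

    plane_depths = [(p + 0.5) * dz for p in range(params.n_planes)]
    for p, zc in enumerate(plane_depths):
        for key in lattice_nodes:
            x, y = pos[key]
            add_node(
                cap_id(p, key),
                x * scale + rng.normal(0, jitter),
                y * scale + rng.normal(0, jitter),
                max(zc + rng.normal(0, 0.3 * jitter), 1.5),
            )
        for a, b in lattice_edges:
            add_vessel(cap_id(p, a), cap_id(p, b), params.capillary_d.sample(rng)[0], "capillary")
        # optional degree-4 (trifurcation-like) shortcuts
        if params.trifurcation_fraction > 0:
            n_extra = int(params.trifurcation_fraction * len(lattice_nodes))
            adj = {k: set(hexg[k]) for k in lattice_nodes}
            for _ in range(n_extra):
                a = lattice_nodes[rng.integers(len(lattice_nodes))]
                two_hop = sorted({w for u in adj[a] for w in adj[u]} - adj[a] - {a})
                if two_hop:
                    b = two_hop[rng.integers(len(two_hop))]
                    add_vessel(cap_id(p, a), cap_id(p, b), params.capillary_d.sample(rng)[0], "capillary")

    # vertical capillary links between adjacent planes
    n_links = max(1, int(params.vertical_link_fraction * len(lattice_nodes)))
    for p in range(params.n_planes - 1):
        chosen = rng.choice(len(lattice_nodes), size=n_links, replace=False)
        for ci in sorted(chosen):
            key = lattice_nodes[ci]
            add_vessel(cap_id(p, key), cap_id(p + 1, key), params.capillary_d.sample(rng)[0],
                       "capillary", tortuosity=float(np.clip(rng.normal(1.12, 0.05), 1.02, 1.4)))

    xs = [n.x for n in nodes.values()]
    ys = [n.y for n in nodes.values()]
    xlim = (min(xs) + scale, max(xs) - scale)
    ylim = (min(ys) + scale, max(ys) - scale)

    # xy positions of lattice columns for nearest-offshoot lookup
    col_xy = np.array([[pos[k][0] * scale, pos[k][1] * scale] for k in lattice_nodes])
    used_targets: set[str] = set()

    def nearest_free(p: int, x: float, y: float) -> str:
        order = np.argsort((col_xy[:, 0] - x) ** 2 + (col_xy[:, 1] - y) ** 2)
        for ci in order:
            nid = cap_id(p, lattice_nodes[int(ci)])
            if nid not in used_targets:
                used_targets.add(nid)
                return nid
        return cap_id(p, lattice_nodes[int(order[0])])  # pragma: no cover - lattice exhausted

    # ---- trunks ------------------------------------------------------
    placed: list[tuple[float, float]] = []
    art_xy = _spread_positions(rng, params.n_arterioles, xlim, ylim, placed)
    placed += art_xy
    ven_xy = _spread_positions(rng, params.n_ascending_venules, xlim, ylim, placed)
    placed += ven_xy
    pcv_xy = _spread_positions(rng, params.n_pcv, xlim, ylim, placed)

    def build_trunk(tag: str, x: float, y: float, depth: float, base_d: float, trunk_type: str,
                    offshoot_spec: DiameterSpec, offshoot_type: str, min_offshoot_z: float = 0.0) -> None:
        top = add_node(f"{tag}_z0", x, y, 0.0)
        prev = top
        kmax = max(1, int(round(depth / dz)))
        last = prev
        for k in range(kmax):
            zc = plane_depths[min(k, params.n_planes - 1)]
            if zc > depth + 0.5 * dz:
                break
            nid = add_node(f"{tag}_k{k}", x + rng.normal(0, 4.0), y + rng.normal(0, 4.0), zc)
            d_here = base_d * (1.0 - params.trunk_taper * zc / params.max_depth_um)
            add_vessel(prev, nid, d_here, trunk_type, tortuosity=1.03)
            if zc >= min_offshoot_z:
                target = nearest_free(min(k, params.n_planes - 1), x, y)
                add_vessel(nid, target, offshoot_spec.sample(rng)[0], offshoot_type,
                           tortuosity=float(np.clip(rng.normal(1.15, 0.05), 1.02, 1.4)))
            prev = nid
            last = nid
        # cut trunk end below the surface: explicit in/outflow candidate
        nodes[last] = NetworkNode(last, nodes[last].x, nodes[last].y, nodes[last].z, True)
        # pial stub at the surface ending in a surface boundary node
        ang = rng.uniform(0, 2 * math.pi)
        stub_len = 80.0
        pial_type = "pial_artery" if trunk_type == "penetrating_arteriole" else "pial_vein"
        pial_d = params.pial_artery_d if pial_type == "pial_artery" else params.pial_vein_d
        bnode = add_node(f"{tag}_pial", x + stub_len * math.cos(ang), y + stub_len * math.sin(ang), 0.0, True)
        add_vessel(top, bnode, pial_d, pial_type, tortuosity=1.05)

    for i, (x, y) in enumerate(art_xy):
        depth = rng.uniform(0.65, 1.0) * params.max_depth_um
        build_trunk(f"a{i}", x, y, depth, params.arteriole_trunk_d.sample(rng)[0],
                    "penetrating_arteriole", params.arteriole_offshoot_d, "arteriole_offshoot")
    for i, (x, y) in enumerate(ven_xy):
        depth = rng.uniform(0.5, 0.9) * params.max_depth_um
        build_trunk(f"u{i}", x, y, depth, params.venule_trunk_d.sample(rng)[0],
                    "ascending_venule", params.venule_offshoot_d, "venule_offshoot")
    for i, (x, y) in enumerate(pcv_xy):
        # PCV-like: full-depth trunk, offshoots restricted to the deep layers,
        # but a couple of shallow drains keep the upper bed perfusable even
        # with few ascending venules.
        build_trunk(f"p{i}", x, y, params.max_depth_um, params.pcv_trunk_d.sample(rng)[0],
                    "ascending_venule", params.venule_offshoot_d, "venule_offshoot",
                    min_offshoot_z=params.pcv_min_offshoot_depth_um)

    net = VascularNetwork(nodes.values(), vessels, name=name or f"synthetic_seed{seed}", validate=False)
    net = _prune_unreachable(net)
    return net


def _prune_unreachable(net: VascularNetwork) -> VascularNetwork:
    """Drop components not reachable from any boundary node (rare jitter artifacts)."""
    g = net.graph()
    reached: set[str] = set()
    for b in net.boundary_nodes():
        if b.id in g and b.id not in reached:
            reached |= nx.node_connected_component(g, b.id)
    kept_vessels = [v for v in net.vessels.values() if v.node_a in reached]
    kept_nodes = [n for n in net.nodes.values() if n.id in reached]
    return VascularNetwork(kept_nodes, kept_vessels, name=net.name)


# ----------------------------------------------------------------------
# Topology summary


@dataclass
class TopologySummary:
    counts_by_type: dict[str, int]
    length_by_type: dict[str, float]
    length_by_layer: dict[str, float]
    capillary_length_fraction: float
    n_boundary_nodes: int
    n_surface_boundary_nodes: int
    total_length_um: float
    n_vessels: int


def topology_summary(net: VascularNetwork, surface_z_um: float = 1.0) -> TopologySummary:
    """Counts, lengths per type and per layer, and the capillary length share."""
    counts: dict[str, int] = {}
    lengths: dict[str, float] = {}
    for v in net.vessels.values():
        counts[v.type] = counts.get(v.type, 0) + 1
        lengths[v.type] = lengths.get(v.type, 0.0) + v.length
    layers = assign_layers(net)
    by_layer = {layer.label: 0.0 for layer in CORTICAL_LAYERS}
    for vid, v in net.vessels.items():
        by_layer[layers[vid].label] += v.length
    total = sum(lengths.values())
    cap_frac = lengths.get("capillary", 0.0) / total if total else 0.0
    boundary = net.boundary_nodes()
    return TopologySummary(
        counts_by_type=dict(sorted(counts.items())),
        length_by_type=dict(sorted(lengths.items())),
        length_by_layer=by_layer,
        capillary_length_fraction=cap_frac,
        n_boundary_nodes=len(boundary),
        n_surface_boundary_nodes=sum(1 for n in boundary if n.z <= surface_z_um),
        total_length_um=total,
        n_vessels=len(net.vessels),
    )


def params_provenance(params: GeneratorParams, seed: int) -> dict:
    d = asdict(params)
    return {"generator_params": d, "seed": seed}
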