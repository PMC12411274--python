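"""Aging perturbation scenarios: capillary eligibility, constriction, rarefaction.

Reproduces the perturbation procedure applied to the reconstructed
networks: capillaries eligible for alteration must lie within the 5th to
95th percentiles of all vessel depths, at least two branches from any
in/outflow, and — to target the venous end of the capillary bed — have a
median topological distance along flow-directed paths of more than 3
segments to the nearest penetrating-arteriole trunk (medianDistMainDA)
and more than 1 segment to the nearest ascending-venule trunk
(medianDistMainAV). Scenarios then scale eligible capillary diameters per
cortical layer, and capillary regression (rarefaction) constricts
randomly selected short (<= 70 µm) eligible capillaries by 97%, which
effectively removes them from the perfused network.
"""

from __future__ import annotations

import math
import sys
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .flow import FlowState
from .network import VascularNetwork, Vessel, assign_layers, vessel_depth

__all__ = [
    "EligibilityCriteria",
    "RegressionSpec",
    "Scenario",
    "SelectionError",
    "ANESTHETIZED_AGED",
    "AWAKE_AGED",
    "CONSTRICTION_ONLY",
    "RAREFACTION_ONLY",
    "median_topological_distances",
    "eligible_capillaries",
    "select_regression_candidates",
    "apply_scenario",
]


class SelectionError(RuntimeError):
    """Regression candidate pool smaller than the required draw."""


@dataclass(frozen=True)
class EligibilityCriteria:
    """Thresholds selecting capillaries safe to perturb.

    depth percentile window and boundary distance guard against
    boundary-condition artifacts; the trunk-distance thresholds select
    capillaries toward the venous end of the bed.
    """

    depth_pct_low: float = 5.0
    depth_pct_high: float = 95.0
    min_branches_from_boundary: int = 2
    min_dist_main_da: float = 3.0  # strict: medianDistMainDA > this
    min_dist_main_av: float = 1.0  # strict: medianDistMainAV > this
    max_path_segments: int = 25


@dataclass(frozen=True)
class RegressionSpec:
    target_density_fraction: float = 0.10
    max_candidate_length_um: float = 70.0
    constriction_fraction: float = 0.97  # diameter scaled by (1 - this)
    n_replicates: int = 5
    layer: str = "L6"


@dataclass(frozen=True)
class Scenario:
    """A named perturbation: per-layer diameter scale factors + optional rarefaction."""

    name: str
    layer_scale: dict[str, float] = field(default_factory=dict)  # layer label -> multiplicative factor
    regression: RegressionSpec | None = None
    criteria: EligibilityCriteria = EligibilityCriteria()

    def __post_init__(self):
        for layer, s in self.layer_scale.items():
            if s <= 0:
                raise ValueError(f"scale factor for {layer} must be positive, got {s}")


#: Anesthetized aged state: 7% constriction of eligible L6 capillaries.
ANESTHETIZED_AGED = Scenario("anesthetized_aged", layer_scale={"L6": 0.93})
#: Awake aged state: 4.5% dilation L2/3, 5.1% dilation L4, 14% constriction
#: plus 10% density reduction in L6.
AWAKE_AGED = Scenario(
    "awake_aged",
    layer_scale={"L2_3": 1.045, "L4": 1.051, "L6": 0.86},
    regression=RegressionSpec(),
)
#: The two L6 effects applied separately.
CONSTRICTION_ONLY = Scenario("constriction_only", layer_scale={"L6": 0.86})
RAREFACTION_ONLY = Scenario("rarefaction_only", regression=RegressionSpec())

NAMED_SCENARIOS = {
    s.name: s for s in (ANESTHETIZED_AGED, AWAKE_AGED, CONSTRICTION_ONLY, RAREFACTION_ONLY)
}


# ----------------------------------------------------------------------
# Flow-directed topological distances to the penetrating trunks


def _directed_graph(net: VascularNetwork, flow: FlowState) -> nx.MultiDiGraph:
    """Orient every vessel along its flow; zero-flow vessels are dropped."""
    g = nx.MultiDiGraph()
    for nid in net.nodes:
        g.add_node(nid)
    for vid, v in net.vessels.items():
        q = flow.flow[vid]
        if q > 0:
            g.add_edge(v.node_a, v.node_b, key=vid, vessel=v)
        elif q < 0:
            g.add_edge(v.node_b, v.node_a, key=vid, vessel=v)
    return g


def _path_length_counts(
    g: nx.MultiDiGraph,
    trunk_nodes: frozenset[str],
    upstream: bool,
    max_segments: int,
) -> dict[str, np.ndarray]:
    """Per-node counts of flow-directed paths to the trunk, by segment count.

    Because pressure decreases strictly along the flow, the flow-directed
    graph is acyclic, so the full path-length distribution (equivalent to
    exhaustive path enumeration) can be computed by dynamic programming:
    a trunk node contributes the zero-length path and absorbs (paths stop
    at the first trunk contact); otherwise a node's distribution is the
    sum of its upstream (or downstream) neighbours' shifted by one
    segment, truncated at ``max_segments``. Should a residual numerical
    cycle appear, its back edge contributes no paths.
    """
    memo: dict[str, np.ndarray] = {}
    in_progress: set[str] = set()
    zero = np.zeros(max_segments + 1)
    sys.setrecursionlimit(max(sys.getrecursionlimit(), 4 * g.number_of_nodes() + 1000))

    def neighbours(node: str):
        edges = g.in_edges(node, keys=True) if upstream else g.out_edges(node, keys=True)
        return [(u if upstream else v) for u, v, _ in edges]

    def counts(node: str) -> np.ndarray:
        cached = memo.get(node)
        if cached is not None:
            return cached
        if node in trunk_nodes:
            c = zero.copy()
            c[0] = 1.0
            memo[node] = c
            return c
        if node in in_progress:
            return zero  # numerical cycle: no path through this edge
        in_progress.add(node)
        c = zero.copy()
        for nxt in neighbours(node):
            c[1:] += counts(nxt)[:-1]
        in_progress.discard(node)
        memo[node] = c
        return c

    for node in g.nodes:
        counts(node)
    return memo


def _median_from_counts(c: np.ndarray) -> float:
    """Median of the multiset {k with multiplicity c[k]}."""
    total = c.sum()
    if total == 0:
        return math.inf
    cum = np.cumsum(c)

    def value_at(i: float) -> int:  # i-th order statistic, 0-based
        return int(np.searchsorted(cum, i, side="right"))

    m1 = value_at((total - 1) / 2.0)
    m2 = value_at(total / 2.0)
    return 0.5 * (m1 + m2)


def _trunk_nodes(net: VascularNetwork, vtype: str) -> frozenset[str]:
    out = set()
    for v in net.vessels.values():
        if v.type == vtype:
            out.add(v.node_a)
            out.add(v.node_b)
    return frozenset(out)


def median_topological_distances(
    net: VascularNetwork,
    flow: FlowState,
    criteria: EligibilityCriteria = EligibilityCriteria(),
) -> dict[str, tuple[float, float]]:
    """Per-capillary (medianDistMainDA, medianDistMainAV) in segment counts.

    For each capillary, all flow-directed simple paths from its upstream
    node to the nearest penetrating-arteriole trunk node are enumerated
    (bounded at ``criteria.max_path_segments`` segments) and the median
    pathlength recorded; analogously downstream to the ascending-venule
    trunk. A capillary directly attached to an offshoot on the trunk gets
    distance 1 (the offshoot is the single intervening segment).
    Capillaries with no bounded path to a trunk map to (inf, inf) and are
    excluded downstream.
    """
    g = _directed_graph(net, flow)
    da_nodes = _trunk_nodes(net, "penetrating_arteriole")
    av_nodes = _trunk_nodes(net, "ascending_venule")
    up_counts = _path_length_counts(g, da_nodes, True, criteria.max_path_segments)
    down_counts = _path_length_counts(g, av_nodes, False, criteria.max_path_segments)
    out: dict[str, tuple[float, float]] = {}
    for vid, v in net.vessels.items():
        if v.type != "capillary":
            continue
        q = flow.flow[vid]
        if q == 0:
            out[vid] = (math.inf, math.inf)
            continue
        up_node = v.node_a if q > 0 else v.node_b
        down_node = v.node_b if q > 0 else v.node_a
        out[vid] = (_median_from_counts(up_counts[up_node]), _median_from_counts(down_counts[down_node]))
    return out


# ----------------------------------------------------------------------
# Eligibility


def _boundary_node_distances(net: VascularNetwork) -> dict[str, int]:
    """BFS edge-distance of every node from the nearest boundary node."""
    g = net.graph()
    dist = {nid: math.inf for nid in net.nodes}
    frontier = [n.id for n in net.boundary_nodes()]
    for nid in frontier:
        dist[nid] = 0
    d = 0
    seen = set(frontier)
    while frontier:
        nxt = []
        d += 1
        for nid in frontier:
            for nb in g[nid]:
                if nb not in seen:
                    seen.add(nb)
                    dist[nb] = d
                    nxt.append(nb)
        frontier = nxt
    return dist


def eligible_capillaries(
    net: VascularNetwork,
    flow: FlowState,
    criteria: EligibilityCriteria = EligibilityCriteria(),
    layer: str | None = None,
    distances: dict[str, tuple[float, float]] | None = None,
) -> set[str]:
    """Capillaries passing the depth-percentile, boundary-distance,
    trunk-distance and (optional) layer filters."""
    depths_all = np.array([vessel_depth(v, net) for v in net.vessels.values()])
    lo = np.percentile(depths_all, criteria.depth_pct_low)
    hi = np.percentile(depths_all, criteria.depth_pct_high)
    if distances is None:
        distances = median_topological_distances(net, flow, criteria)
    node_dist = _boundary_node_distances(net)
    layers = assign_layers(net)
    chosen: set[str] = set()
    for vid, v in net.vessels.items():
        if v.type != "capillary":
            continue
        d = vessel_depth(v, net)
        if not lo <= d <= hi:
            continue
        # number of intermediate vessels between this capillary and the
        # nearest boundary node = min endpoint BFS distance
        if min(node_dist[v.node_a], node_dist[v.node_b]) < criteria.min_branches_from_boundary:
            continue
        da, av = distances.get(vid, (math.inf, math.inf))
        if not (math.isfinite(da) and math.isfinite(av)):
            continue
        if not (da > criteria.min_dist_main_da and av > criteria.min_dist_main_av):
            continue
        if layer is not None and layers[vid].label != layer:
            continue
        chosen.add(vid)
    return chosen


# ----------------------------------------------------------------------
# Regression selection and scenario application


def select_regression_candidates(
    net: VascularNetwork,
    eligible: set[str],
    max_length_um: float,
    target_fraction: float,
    layer_capillary_total: int,
    seed: int,
) -> list[str]:
    """Uniform draw (without replacement) of capillaries to regress.

    The draw count is the integer part of target_fraction times the layer's
    total capillary count; the pool is the eligible set restricted to
    capillaries of at most max_length_um.
    """
    pool = sorted(vid for vid in eligible if net.vessels[vid].length <= max_length_um)
    n_draw = int(target_fraction * layer_capillary_total)
    if n_draw == 0:
        return []
    if len(pool) < n_draw:
        raise SelectionError(f"regression pool has {len(pool)} candidates but {n_draw} are required")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=n_draw, replace=False)
    return [pool[i] for i in sorted(picked)]


@dataclass
class PerturbedNetwork:
    network: VascularNetwork
    scenario: str
    replicate_seed: int | None
    scaled_vessels: dict[str, float]  # vessel id -> scale factor applied
    regressed_vessels: list[str]


def apply_scenario(
    net: VascularNetwork,
    scenario: Scenario,
    flow: FlowState,
    seeds: list[int] | None = None,
) -> list[PerturbedNetwork]:
    """Apply per-layer diameter scaling and (optionally) capillary regression.

    Scaling is deterministic and identical across replicates; replicates
    differ only in the random regression draw. Returns one perturbed
    network per replicate seed (a single network when the scenario has no
    regression component). Non-capillary vessels are never modified.
    """
    crit = scenario.criteria
    distances = median_topological_distances(net, flow, crit)
    layers = assign_layers(net)

    scale_map: dict[str, float] = {}
    for layer, factor in scenario.layer_scale.items():
        for vid in eligible_capillaries(net, flow, crit, layer=layer, distances=distances):
            scale_map[vid] = factor

    if scenario.regression is None:
        replicate_seeds: list[int | None] = [None]
    else:
        if seeds is None:
            seeds = list(range(scenario.regression.n_replicates))
        replicate_seeds = list(seeds)

    out: list[PerturbedNetwork] = []
    for rep_seed in replicate_seeds:
        regressed: list[str] = []
        if scenario.regression is not None:
            spec = scenario.regression
            elig_layer = eligible_capillaries(net, flow, crit, layer=spec.layer, distances=distances)
            total = sum(
                1 for vid, v in net.vessels.items()
                if v.type == "capillary" and layers[vid].label == spec.layer
            )
            regressed = select_regression_candidates(
                net, elig_layer, spec.max_candidate_length_um, spec.target_density_fraction, total, rep_seed
            )
        new_vessels = []
        for vid, v in net.vessels.items():
            d = v.diameter
            if vid in regressed:
                d = v.diameter * (1.0 - scenario.regression.constriction_fraction)
            elif vid in scale_map:
                d = v.diameter * scale_map[vid]
            new_vessels.append(replace(v, diameter=d) if d != v.diameter else v)
        pert = VascularNetwork(net.nodes.values(), new_vessels,
                               name=f"{net.name}__{scenario.name}"
                                    + (f"_rep{rep_seed}" if rep_seed is not None else ""),
                               validate=False)
        out.append(PerturbedNetwork(pert, scenario.name, rep_seed, dict(scale_map), regressed))
    return out
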