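"""Drainage-network taxonomy: bifurcation classes, pre-convergence capillaries, tributaries.

On the venous side of the capillary bed, blood merges at convergent
bifurcations. A *pre-convergence capillary* is the segment between the
last divergent and the first convergent bifurcation of an arteriovenous
path; downstream of it, *other tributary vessels* are connected
exclusively by convergence points until the drainage attaches to a
venule branch. The pre-convergence capillaries plus their downstream
convergence-only vessels form a *tributary*.

Because capillary networks are bifurcation-dominated, the number of
segments in a tributary is almost always odd (a full binary drainage
tree with k leaves has 2k-1 segments); tributaries containing a
trifurcation can have an even count, which is classed as the next higher
odd number. Complexity classes: low (1 or 3 segments), medium (5 or 7),
high (9 or more).

Degree-2 ("through") nodes are transparent: consecutive vessels joined
only by through nodes count as a single segment, matching the
bifurcation-delimited segments of in vivo reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .flow import FlowState
from .network import VascularNetwork

__all__ = [
    "TributaryTopologyError",
    "classify_bifurcations",
    "Tributary",
    "TributarySegment",
    "extract_tributaries",
    "tributary_complexity",
    "tributary_summary",
]

COMPLEXITY_CLASSES = ("low", "medium", "high")


class TributaryTopologyError(RuntimeError):
    """Cycle encountered while walking a tributary upstream."""


def _flow_orientation(net: VascularNetwork, flow: FlowState):
    """Per-node inflow/outflow vessel lists under the given flow field."""
    inflows: dict[str, list[str]] = {nid: [] for nid in net.nodes}
    outflows: dict[str, list[str]] = {nid: [] for nid in net.nodes}
    zero_touch: set[str] = set()
    for vid, v in net.vessels.items():
        q = flow.flow[vid]
        if q > 0:
            outflows[v.node_a].append(vid)
            inflows[v.node_b].append(vid)
        elif q < 0:
            outflows[v.node_b].append(vid)
            inflows[v.node_a].append(vid)
        else:
            zero_touch.add(v.node_a)
            zero_touch.add(v.node_b)
    return inflows, outflows, zero_touch


def classify_bifurcations(net: VascularNetwork, flow: FlowState) -> dict[str, str]:
    """Label every node divergent / convergent / through / unclassified.

    divergent: one inflow, two or more outflows; convergent: two or more
    inflows, one outflow; through: one in, one out. Nodes touching a
    zero-flow vessel (direction undefined) and all remaining patterns
    (boundary terminals, mixed degree-4 nodes) are unclassified.
    """
    inflows, outflows, zero_touch = _flow_orientation(net, flow)
    labels: dict[str, str] = {}
    for nid in net.nodes:
        n_in, n_out = len(inflows[nid]), len(outflows[nid])
        if nid in zero_touch:
            labels[nid] = "unclassified"
        elif n_in == 1 and n_out >= 2:
            labels[nid] = "divergent"
        elif n_in >= 2 and n_out == 1:
            labels[nid] = "convergent"
        elif n_in == 1 and n_out == 1:
            labels[nid] = "through"
        else:
            labels[nid] = "unclassified"
    return labels


@dataclass(frozen=True)
class TributarySegment:
    """One bifurcation-delimited segment (possibly several through-joined vessels)."""

    vessels: tuple[str, ...]
    cls: str  # 'pre_convergence' | 'other_tributary'

    def length(self, net: VascularNetwork) -> float:
        return sum(net.vessels[vid].length for vid in self.vessels)


@dataclass
class Tributary:
    attachment_vessel: str
    segments: list[TributarySegment] = field(default_factory=list)
    shared_truncated: bool = False  # lost segments to a closer tributary

    @property
    def member_classes(self) -> dict[str, str]:
        return {vid: seg.cls for seg in self.segments for vid in seg.vessels}

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_segments_effective(self) -> int:
        """Segment count with the even-to-next-odd (trifurcation) convention."""
        n = self.n_segments
        return n + 1 if n % 2 == 0 and n > 0 else n

    @property
    def complexity(self) -> str:
        return tributary_complexity(self.n_segments)


def tributary_complexity(n_segments: int) -> str:
    """Complexity class of a tributary from its raw segment count."""
    if n_segments < 1:
        raise ValueError(f"segment count must be >= 1, got {n_segments}")
    n = n_segments + 1 if n_segments % 2 == 0 else n_segments
    if n <= 3:
        return "low"
    if n <= 7:
        return "medium"
    return "high"


def extract_tributaries(
    net: VascularNetwork,
    flow: FlowState,
    branch_vessel_ids: list[str],
) -> list[Tributary]:
    """Walk upstream from each branch attachment, collecting its tributary.

    From the upstream node of each attachment vessel, every inflowing
    segment (through-nodes merged) is collected: if the segment's own
    upstream node is convergent the segment is an *other tributary vessel*
    and the walk recurses; otherwise (divergent, boundary, unclassified)
    the segment is a *pre-convergence capillary* and the walk stops —
    vessels upstream of the last divergence are not tributary members.

    If two attachments compete for the same segment (impossible in a
    tree), the one with fewer hops downstream keeps it and both
    tributaries are flagged ``shared_truncated``.
    """
    inflows, outflows, _ = _flow_orientation(net, flow)
    labels = classify_bifurcations(net, flow)

    def upstream_node(vid: str) -> str:
        v = net.vessels[vid]
        return v.node_a if flow.flow[vid] > 0 else v.node_b

    # independent walks, recording each segment's hop depth and parent
    walks: dict[str, list[tuple[TributarySegment, int, int | None]]] = {}
    for branch in branch_vessel_ids:
        if flow.flow[branch] == 0:
            walks[branch] = []
            continue
        segments: list[tuple[TributarySegment, int, int | None]] = []
        visited_nodes: set[str] = set()

        def collect(node: str, depth: int, parent: int | None) -> None:
            if node in visited_nodes:
                raise TributaryTopologyError(f"cycle at node {node!r} walking upstream of {branch!r}")
            visited_nodes.add(node)
            for vid in inflows[node]:
                chain = [vid]
                up = upstream_node(vid)
                while labels[up] == "through":
                    (vid2,) = inflows[up]
                    chain.append(vid2)
                    if up in visited_nodes:
                        raise TributaryTopologyError(f"cycle at node {up!r} walking upstream of {branch!r}")
                    visited_nodes.add(up)
                    up = upstream_node(vid2)
                idx = len(segments)
                if labels[up] == "convergent":
                    segments.append((TributarySegment(tuple(chain), "other_tributary"), depth, parent))
                    collect(up, depth + 1, idx)
                else:
                    segments.append((TributarySegment(tuple(chain), "pre_convergence"), depth, parent))

        collect(upstream_node(branch), 0, None)
        walks[branch] = segments

    # resolve overlaps: closest-downstream attachment wins a shared segment
    owner: dict[tuple[str, ...], tuple[int, str]] = {}
    for branch, segs in walks.items():
        for seg, depth, _ in segs:
            key = seg.vessels
            if key not in owner or (depth, branch) < owner[key]:
                owner[key] = (depth, branch)

    out: list[Tributary] = []
    for branch in branch_vessel_ids:
        trib = Tributary(attachment_vessel=branch)
        segs = walks[branch]
        lost = [False] * len(segs)
        for i, (seg, depth, parent) in enumerate(segs):
            inherited_loss = parent is not None and lost[parent]
            if inherited_loss or owner[seg.vessels][1] != branch:
                lost[i] = True
                trib.shared_truncated = True
                continue
            trib.segments.append(seg)
        out.append(trib)
    return out


def tributary_summary(tributaries: list[Tributary], net: VascularNetwork) -> dict:
    """Aggregate shares of pre-convergence segments/length and complexity mix."""
    if not tributaries:
        return {
            "n_tributaries": 0,
            "pct_segments_preconvergence": float("nan"),
            "pct_length_preconvergence": float("nan"),
            "complexity_fractions": {c: float("nan") for c in COMPLEXITY_CLASSES},
            "tributaries_per_branch": float("nan"),
        }
    n_seg = n_pre = 0
    len_total = len_pre = 0.0
    comp_counts = {c: 0 for c in COMPLEXITY_CLASSES}
    for t in tributaries:
        for seg in t.segments:
            n_seg += 1
            length = seg.length(net)
            len_total += length
            if seg.cls == "pre_convergence":
                n_pre += 1
                len_pre += length
        if t.segments:
            comp_counts[t.complexity] += 1
    n_with_segments = sum(1 for t in tributaries if t.segments)
    branches = {t.attachment_vessel for t in tributaries}
    return {
        "n_tributaries": len(tributaries),
        "pct_segments_preconvergence": 100.0 * n_pre / n_seg if n_seg else float("nan"),
        "pct_length_preconvergence": 100.0 * len_pre / len_total if len_total else float("nan"),
        "complexity_fractions": {
            c: comp_counts[c] / n_with_segments if n_with_segments else float("nan")
            for c in COMPLEXITY_CLASSES
        },
        "tributaries_per_branch": len(tributaries) / len(branches) if branches else float("nan"),
    }
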