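"""Drainage taxonomy: bifurcation classes, tributary extraction vs brute force, complexity."""

import itertools

import networkx as nx
import pytest

from mvnflow import (
    Tributary,
    classify_bifurcations,
    extract_tributaries,
    tributary_complexity,
    tributary_summary,
)
from mvnflow.flow import FlowState
from mvnflow.tributaries import TributarySegment

from conftest import mknet


def state(net, flow) -> FlowState:
    return FlowState(
        pressure={nid: 0.0 for nid in net.nodes},
        flow=dict(flow),
        discharge_hct={vid: 0.3 for vid in net.vessels},
        tube_hct={vid: 0.25 for vid in net.vessels},
        rbc_velocity={vid: 100.0 for vid in net.vessels},
    )


def binary_drainage_net(n_leaves: int, merge_arity: int = 2):
    """A drainage tree: n_leaves pre-convergence capillaries fed from
    divergent nodes, merging (pairwise by default) into a venule branch.

    Returns (net, flow_state, branch_vessel_id, feeder_ids, member_ids).
    """
    nodes, vessels, flow = [], [], {}
    # each leaf is fed by a divergent node: feeder in, leaf + spill out
    leaf_roots = []
    for i in range(n_leaves):
        nodes += [
            (f"src{i}", 0, 0, 0, True), (f"div{i}", 0, 0, 0, False),
            (f"spill_end{i}", 0, 0, 0, True), (f"top{i}", 0, 0, 0, False),
        ]
        vessels += [
            (f"feed{i}", f"src{i}", f"div{i}", 8.0, 10.0, "arteriole_offshoot"),
            (f"spill{i}", f"div{i}", f"spill_end{i}", 4.0, 10.0, "capillary"),
            (f"leaf{i}", f"div{i}", f"top{i}", 4.0, 10.0, "capillary"),
        ]
        flow |= {f"feed{i}": 2.0, f"spill{i}": 1.0, f"leaf{i}": 1.0}
        leaf_roots.append((f"top{i}", 1.0, f"leaf{i}"))
    # merge in groups of merge_arity down to a single root
    queue = leaf_roots
    k = 0
    while len(queue) > 1:
        group, queue = queue[:merge_arity], queue[merge_arity:]
        if len(group) == 1:
            queue.append(group[0])
            continue
        nid = f"merge{k}"
        nodes.append((nid, 0, 0, 0, False))
        q_sum = sum(q for _, q, _ in group)
        for node, _, _ in group:
            # reuse the incoming vessel's downstream node as the merge node
            pass
        # connect each group member's head node into the merge node
        out_id = f"seg{k}"
        for node, q, vid in group:
            # the member's vessel already ends at `node`; bridge it into nid
            vessels.append((f"b_{node}", node, nid, 4.0, 1e-9, "capillary"))
            flow[f"b_{node}"] = q
        k += 1
        end = f"segend{k}"
        nodes.append((end, 0, 0, 0, False))
        vessels.append((out_id, nid, end, 4.0, 10.0, "capillary"))
        flow[out_id] = q_sum
        queue.append((end, q_sum, out_id))
    root_node, root_q, _ = queue[0]
    nodes.append(("sink", 0, 0, 0, True))
    vessels.append(("branch", root_node, "sink", 12.0, 10.0, "ascending_venule"))
    flow["branch"] = root_q
    net = mknet(nodes, vessels, validate=False)
    return net, state(net, flow)


class TestClassifyBifurcations:
    def _toy(self):
        nodes = [("a", 0, 0, 0, True), ("n", 0, 0, 0, False), ("b", 0, 0, 0, True),
                 ("c", 0, 0, 0, True)]
        vessels = [
            ("v1", "a", "n", 4.0, 10.0, "capillary"),
            ("v2", "n", "b", 4.0, 10.0, "capillary"),
            ("v3", "n", "c", 4.0, 10.0, "capillary"),
        ]
        return mknet(nodes, vessels, validate=False)

    def test_one_in_two_out_is_divergent(self):
        net = self._toy()
        labels = classify_bifurcations(net, state(net, {"v1": 2.0, "v2": 1.0, "v3": 1.0}))
        assert labels["n"] == "divergent"

    def test_two_in_one_out_is_convergent(self):
        net = self._toy()
        labels = classify_bifurcations(net, state(net, {"v1": 2.0, "v2": -1.0, "v3": 3.0}))
        assert labels["n"] == "convergent"

    def test_one_in_one_out_is_through(self):
        nodes = [("a", 0, 0, 0, True), ("n", 0, 0, 0, False), ("b", 0, 0, 0, True)]
        vessels = [("v1", "a", "n", 4.0, 10.0, "capillary"),
                   ("v2", "n", "b", 4.0, 10.0, "capillary")]
        net = mknet(nodes, vessels, validate=False)
        labels = classify_bifurcations(net, state(net, {"v1": 1.0, "v2": 1.0}))
        assert labels["n"] == "through"

    def test_zero_flow_vessel_unclassifies_node(self):
        net = self._toy()
        labels = classify_bifurcations(net, state(net, {"v1": 2.0, "v2": 0.0, "v3": 2.0}))
        assert labels["n"] == "unclassified"

    def test_duality_under_flow_reversal(self):
        net = self._toy()
        fwd = classify_bifurcations(net, state(net, {"v1": 2.0, "v2": 1.0, "v3": 1.0}))
        rev = classify_bifurcations(net, state(net, {"v1": -2.0, "v2": -1.0, "v3": -1.0}))
        swap = {"divergent": "convergent", "convergent": "divergent"}
        for nid in net.nodes:
            assert rev[nid] == swap.get(fwd[nid], fwd[nid])


def brute_force_members(net, flow, branch: str) -> dict[str, str]:
    """Independent oracle: tributary membership by exhaustive path enumeration.

    A vessel belongs to the branch's tributary iff some flow-directed path
    carries it to the branch with every intermediate junction convergent
    (or a plain through node); its class is read off its upstream node.
    """
    g = nx.MultiDiGraph()
    for vid, v in net.vessels.items():
        q = flow.flow[vid]
        if q > 0:
            g.add_edge(v.node_a, v.node_b, key=vid)
        elif q < 0:
            g.add_edge(v.node_b, v.node_a, key=vid)
    labels = classify_bifurcations(net, flow)
    v_branch = net.vessels[branch]
    target = v_branch.node_a if flow.flow[branch] > 0 else v_branch.node_b
    members: dict[str, str] = {}
    for vid, v in net.vessels.items():
        if vid == branch or flow.flow[vid] == 0:
            continue
        head = v.node_b if flow.flow[vid] > 0 else v.node_a  # downstream endpoint
        tail = v.node_a if flow.flow[vid] > 0 else v.node_b
        for path in nx.all_simple_paths(g, head, target):
            if all(labels[n] in ("convergent", "through") for n in path[:-1]):
                up = tail
                # walk back through plain through nodes to find the true segment head
                while labels[up] == "through":
                    (pred,) = [u for u, _, k in g.in_edges(up, keys=True)]
                    up = pred
                members[vid] = "other_tributary" if labels[up] == "convergent" else "pre_convergence"
                break
        if head == target and vid not in members:
            up = tail
            while labels[up] == "through":
                (pred,) = [u for u, _, k in g.in_edges(up, keys=True)]
                up = pred
            members[vid] = "other_tributary" if labels[up] == "convergent" else "pre_convergence"
    return members


class TestExtraction:
    def test_minimal_tributary_single_pre_convergence(self):
        net, fs = binary_drainage_net(1)
        (trib,) = extract_tributaries(net, fs, ["branch"])
        assert trib.n_segments == 1
        assert all(seg.cls == "pre_convergence" for seg in trib.segments)

    @pytest.mark.parametrize("n_leaves", [2, 3, 4, 5, 6, 7, 8])
    def test_matches_brute_force_on_drainage_trees(self, n_leaves):
        net, fs = binary_drainage_net(n_leaves)
        (trib,) = extract_tributaries(net, fs, ["branch"])
        oracle = brute_force_members(net, fs, "branch")
        got = {vid: cls for vid, cls in trib.member_classes.items()
               if net.vessels[vid].length > 1e-8}  # drop zero-length bridges
        oracle = {vid: cls for vid, cls in oracle.items() if net.vessels[vid].length > 1e-8}
        assert got == oracle

    @pytest.mark.parametrize("n_leaves", [1, 2, 3, 4, 5, 6, 7, 8])
    def test_bifurcation_trees_have_odd_segment_counts(self, n_leaves):
        net, fs = binary_drainage_net(n_leaves)
        (trib,) = extract_tributaries(net, fs, ["branch"])
        assert trib.n_segments == 2 * n_leaves - 1
        assert trib.n_segments % 2 == 1

    def test_feeders_upstream_of_last_divergence_excluded(self):
        net, fs = binary_drainage_net(4)
        (trib,) = extract_tributaries(net, fs, ["branch"])
        for vid in trib.member_classes:
            assert not vid.startswith("feed")
            assert not vid.startswith("spill")

    def test_trifurcation_gives_even_count_rounded_up(self):
        net, fs = binary_drainage_net(3, merge_arity=3)
        (trib,) = extract_tributaries(net, fs, ["branch"])
        assert trib.n_segments == 4
        assert trib.n_segments_effective == 5
        assert trib.complexity == "medium"

    def test_through_nodes_merge_into_single_segment(self):
        # leaf -> through chain of 3 vessels -> branch: one effective segment
        nodes = [("s", 0, 0, 0, True), ("d", 0, 0, 0, False), ("sp", 0, 0, 0, True),
                 ("t1", 0, 0, 0, False), ("t2", 0, 0, 0, False), ("m", 0, 0, 0, False),
                 ("sink", 0, 0, 0, True)]
        vessels = [
            ("feed", "s", "d", 8.0, 10.0, "arteriole_offshoot"),
            ("spill", "d", "sp", 4.0, 10.0, "capillary"),
            ("c1", "d", "t1", 4.0, 10.0, "capillary"),
            ("c2", "t1", "t2", 4.0, 10.0, "capillary"),
            ("c3", "t2", "m", 4.0, 10.0, "capillary"),
            ("branch", "m", "sink", 12.0, 10.0, "ascending_venule"),
        ]
        net = mknet(nodes, vessels, validate=False)
        fs = state(net, {"feed": 2.0, "spill": 1.0, "c1": 1.0, "c2": 1.0, "c3": 1.0, "branch": 1.0})
        (trib,) = extract_tributaries(net, fs, ["branch"])
        assert trib.n_segments == 1
        assert set(trib.segments[0].vessels) == {"c1", "c2", "c3"}
        assert trib.segments[0].cls == "pre_convergence"


class TestComplexity:
    @pytest.mark.parametrize(
        "count,expected",
        [(1, "low"), (3, "low"), (4, "medium"), (5, "medium"), (6, "medium"),
         (7, "medium"), (8, "high"), (9, "high"), (15, "high")],
    )
    def test_classes_with_even_to_odd_convention(self, count, expected):
        assert tributary_complexity(count) == expected

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            tributary_complexity(0)


class TestSummary:
    def _net_for_lengths(self):
        nodes = [("a", 0, 0, 0, True), ("b", 0, 0, 0, True), ("c", 0, 0, 0, True),
                 ("d", 0, 0, 0, True)]
        vessels = [("p1", "a", "b", 4.0, 50.0, "capillary"),
                   ("p2", "b", "c", 4.0, 50.0, "capillary"),
                   ("o1", "c", "d", 4.0, 25.0, "capillary")]
        return mknet(nodes, vessels, validate=False)

    def test_preconvergence_length_share(self):
        net = self._net_for_lengths()
        trib = Tributary("branch", [
            TributarySegment(("p1",), "pre_convergence"),
            TributarySegment(("p2",), "pre_convergence"),
            TributarySegment(("o1",), "other_tributary"),
        ])
        s = tributary_summary([trib], net)
        assert s["pct_length_preconvergence"] == pytest.approx(80.0)
        assert s["pct_segments_preconvergence"] == pytest.approx(100 * 2 / 3)

    def test_all_preconvergence_is_one_hundred_percent(self):
        net = self._net_for_lengths()
        trib = Tributary("branch", [TributarySegment(("p1",), "pre_convergence")])
        s = tributary_summary([trib], net)
        assert s["pct_length_preconvergence"] == 100.0
        assert s["pct_segments_preconvergence"] == 100.0

    def test_complexity_fractions_sum_to_one(self):
        net, fs = binary_drainage_net(5)
        tribs = extract_tributaries(net, fs, ["branch"])
        s = tributary_summary(tribs, net)
        assert sum(s["complexity_fractions"].values()) == pytest.approx(1.0)

    def test_empty_input_empty_summary(self):
        s = tributary_summary([], None)
        assert s["n_tributaries"] == 0
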