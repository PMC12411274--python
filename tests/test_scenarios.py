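"""Perturbation machinery: trunk distances, eligibility, regression draws, scenarios."""

import math

import numpy as np
import pytest

from mvnflow import (
    AWAKE_AGED,
    ANESTHETIZED_AGED,
    EligibilityCriteria,
    apply_scenario,
    build_boundary_conditions,
    eligible_capillaries,
    median_topological_distances,
    select_regression_candidates,
    solve_flow,
)
from mvnflow.flow import FlowState
from mvnflow.network import VascularNetwork, Vessel, assign_layers
from mvnflow.scenarios import RAREFACTION_ONLY, SelectionError

from conftest import mknet


def unit_flow_state(net: VascularNetwork) -> FlowState:
    """Flow of +1 along every vessel's node_a -> node_b axis."""
    return FlowState(
        pressure={nid: 0.0 for nid in net.nodes},
        flow={vid: 1.0 for vid in net.vessels},
        discharge_hct={vid: 0.3 for vid in net.vessels},
        tube_hct={vid: 0.25 for vid in net.vessels},
        rbc_velocity={vid: 100.0 for vid in net.vessels},
    )


class TestMedianTopologicalDistances:
    def _z(self, *ids, z=0.0, boundary=()):
        return [(i, 0.0, 0.0, z, i in boundary) for i in ids]

    def test_median_over_parallel_upstream_paths(self):
        # three flow-directed paths of 2, 3 and 5 segments from the trunk
        # node to the capillary's upstream node -> medianDistMainDA = 3
        nodes = self._z("t1", "t2", "a1", "b1", "b2", "e1", "e2", "e3", "e4", "u", "w",
                        boundary=("t1", "w"))
        vessels = [
            ("T", "t1", "t2", 15.0, 10.0, "penetrating_arteriole"),
            ("pa1", "t2", "a1", 4.0, 10.0, "capillary"),
            ("pa2", "a1", "u", 4.0, 10.0, "capillary"),
            ("pb1", "t2", "b1", 4.0, 10.0, "capillary"),
            ("pb2", "b1", "b2", 4.0, 10.0, "capillary"),
            ("pb3", "b2", "u", 4.0, 10.0, "capillary"),
            ("pe1", "t2", "e1", 4.0, 10.0, "capillary"),
            ("pe2", "e1", "e2", 4.0, 10.0, "capillary"),
            ("pe3", "e2", "e3", 4.0, 10.0, "capillary"),
            ("pe4", "e3", "e4", 4.0, 10.0, "capillary"),
            ("pe5", "e4", "u", 4.0, 10.0, "capillary"),
            ("cap", "u", "w", 4.0, 10.0, "capillary"),
        ]
        net = mknet(nodes, vessels, validate=False)
        dist = median_topological_distances(net, unit_flow_state(net))
        assert dist["cap"][0] == pytest.approx(3.0)

    def test_adjacent_offshoot_counts_one(self):
        nodes = self._z("t1", "t2", "u", "w", boundary=("t1", "w"))
        vessels = [
            ("T", "t1", "t2", 15.0, 10.0, "penetrating_arteriole"),
            ("off", "t2", "u", 8.0, 10.0, "arteriole_offshoot"),
            ("cap", "u", "w", 4.0, 10.0, "capillary"),
        ]
        net = mknet(nodes, vessels, validate=False)
        dist = median_topological_distances(net, unit_flow_state(net))
        assert dist["cap"][0] == pytest.approx(1.0)

    def test_mirror_symmetric_network_has_equal_distances(self):
        nodes = self._z("t1", "t2", "u", "w", "x", "s1", "s2", boundary=("t1", "s2"))
        vessels = [
            ("T", "t1", "t2", 15.0, 10.0, "penetrating_arteriole"),
            ("offA", "t2", "u", 8.0, 10.0, "arteriole_offshoot"),
            ("cap", "u", "w", 4.0, 10.0, "capillary"),
            ("offV", "w", "x", 8.0, 10.0, "venule_offshoot"),
            ("V", "x", "s1", 15.0, 10.0, "ascending_venule"),
            ("Vout", "s1", "s2", 15.0, 10.0, "pial_vein"),
        ]
        net = mknet(nodes, vessels, validate=False)
        da, av = median_topological_distances(net, unit_flow_state(net))["cap"]
        assert da == av == 1.0

    def test_zero_flow_capillary_marked_unreachable(self):
        nodes = self._z("t1", "t2", "u", "w", boundary=("t1", "w"))
        vessels = [
            ("T", "t1", "t2", 15.0, 10.0, "penetrating_arteriole"),
            ("off", "t2", "u", 8.0, 10.0, "arteriole_offshoot"),
            ("cap", "u", "w", 4.0, 10.0, "capillary"),
        ]
        net = mknet(nodes, vessels, validate=False)
        fs = unit_flow_state(net)
        fs.flow["cap"] = 0.0
        assert median_topological_distances(net, fs)["cap"] == (math.inf, math.inf)


def chain_toy():
    """Layer-6 chain with medianDistMainDA=4 and medianDistMainAV=2 for 'CAP'."""
    depth = 900.0
    ids = ["in", "t", "n0", "n1", "n2", "n3", "n4", "n5", "n6", "vx", "out"]
    nodes = [(i, 0.0, 0.0, depth, i in ("in", "out")) for i in ids]
    vessels = [
        ("A", "in", "t", 15.0, 10.0, "penetrating_arteriole"),
        ("o", "t", "n0", 8.0, 10.0, "arteriole_offshoot"),
        ("c0", "n0", "n1", 4.0, 10.0, "capillary"),
        ("c1", "n1", "n2", 4.0, 10.0, "capillary"),
        ("c2", "n2", "n3", 4.0, 10.0, "capillary"),
        ("CAP", "n3", "n4", 4.0, 10.0, "capillary"),
        ("d1", "n4", "n5", 4.0, 10.0, "capillary"),
        ("d2", "n5", "n6", 4.0, 10.0, "capillary"),
        ("V", "n6", "vx", 15.0, 10.0, "ascending_venule"),
        ("Vp", "vx", "out", 15.0, 10.0, "pial_vein"),
    ]
    net = mknet(nodes, vessels, validate=False)
    return net, unit_flow_state(net)


class TestEligibility:
    def test_distance_thresholds_select_venous_end_capillary(self):
        net, fs = chain_toy()
        dist = median_topological_distances(net, fs)
        assert dist["CAP"] == (4.0, 2.0)
        elig = eligible_capillaries(net, fs, layer="L6")
        assert "CAP" in elig
        # c2 sits at DA=3 (not > 3): excluded despite matching AV
        assert "c2" not in elig

    def test_boundary_proximity_excludes(self):
        # a chain of six capillaries between trunks: the outermost ones sit
        # fewer than two intermediate vessels from an in/outflow boundary
        ids = ["in", "t", "m1", "m2", "m3", "m4", "m5", "v", "out"]
        nodes = [(i, 0.0, 0.0, 300.0, i in ("in", "out")) for i in ids]
        vessels = [
            ("A", "in", "t", 15.0, 10.0, "penetrating_arteriole"),
            ("x1", "t", "m1", 4.0, 10.0, "capillary"),
            ("x2", "m1", "m2", 4.0, 10.0, "capillary"),
            ("x3", "m2", "m3", 4.0, 10.0, "capillary"),
            ("x4", "m3", "m4", 4.0, 10.0, "capillary"),
            ("x5", "m4", "m5", 4.0, 10.0, "capillary"),
            ("x6", "m5", "v", 4.0, 10.0, "capillary"),
            ("V", "v", "out", 15.0, 10.0, "ascending_venule"),
        ]
        net = mknet(nodes, vessels, validate=False)
        crit = EligibilityCriteria(min_dist_main_da=0.0, min_dist_main_av=0.0)
        elig = eligible_capillaries(net, unit_flow_state(net), crit)
        assert elig == {"x2", "x3", "x4", "x5"}

    def test_tightening_thresholds_shrinks_set(self, small_net):
        bc = build_boundary_conditions(small_net, "trimmed")
        fs = solve_flow(small_net, bc, 0.3)
        base = eligible_capillaries(small_net, fs)
        for crit in (
            EligibilityCriteria(min_dist_main_da=5.0),
            EligibilityCriteria(min_dist_main_av=3.0),
            EligibilityCriteria(depth_pct_low=20.0, depth_pct_high=80.0),
            EligibilityCriteria(min_branches_from_boundary=5),
        ):
            assert eligible_capillaries(small_net, fs, crit) <= base


class TestRegressionSelection:
    def _pool_net(self, n, length=50.0):
        nodes, vessels = [], []
        for i in range(n):
            nodes += [(f"a{i}", 0, 0, 850, True), (f"b{i}", 0, 0, 860, True)]
            vessels.append((f"v{i:04d}", f"a{i}", f"b{i}", 4.0, length, "capillary"))
        net = mknet(nodes, vessels, validate=False)
        return net, {v[0] for v in vessels}

    @pytest.mark.parametrize(
        "total,expected",
        [(1707, 170), (1413, 141), (1789, 178), (1737, 173)],
    )
    def test_draw_counts_for_ten_percent_density_reduction(self, total, expected):
        net, pool = self._pool_net(800)
        picked = select_regression_candidates(net, pool, 70.0, 0.10, total, seed=0)
        assert len(picked) == expected

    def test_zero_fraction_selects_nothing(self):
        net, pool = self._pool_net(50)
        assert select_regression_candidates(net, pool, 70.0, 0.0, 500, seed=0) == []

    def test_pool_too_small_raises(self):
        net, pool = self._pool_net(5)
        with pytest.raises(SelectionError):
            select_regression_candidates(net, pool, 70.0, 0.10, 100, seed=0)

    def test_long_capillaries_excluded_from_pool(self):
        net, pool = self._pool_net(50, length=90.0)
        with pytest.raises(SelectionError):
            select_regression_candidates(net, pool, 70.0, 0.10, 100, seed=0)

    def test_replicates_differ_but_are_seed_stable(self):
        net, pool = self._pool_net(100)
        a = select_regression_candidates(net, pool, 70.0, 0.10, 200, seed=1)
        b = select_regression_candidates(net, pool, 70.0, 0.10, 200, seed=2)
        assert a != b
        assert a == select_regression_candidates(net, pool, 70.0, 0.10, 200, seed=1)


@pytest.fixture(scope="module")
def small_flow(small_net):
    bc = build_boundary_conditions(small_net, "trimmed")
    return solve_flow(small_net, bc, 0.3)


class TestApplyScenario:
    def test_awake_scaling_factors_per_layer(self, small_net, small_flow):
        pert = apply_scenario(small_net, AWAKE_AGED, small_flow, seeds=[0])[0]
        layers = assign_layers(small_net)
        factors = {"L2_3": 1.045, "L4": 1.051, "L6": 0.86}
        for vid, factor in pert.scaled_vessels.items():
            assert factor == factors[layers[vid].label]
        regressed = set(pert.regressed_vessels)
        for vid, v in small_net.vessels.items():
            new_d = pert.network.vessels[vid].diameter
            if vid in regressed:
                assert new_d == pytest.approx(v.diameter * 0.03)
            elif vid in pert.scaled_vessels:
                assert new_d == pytest.approx(v.diameter * pert.scaled_vessels[vid])
            else:
                assert new_d == v.diameter

    def test_anesthetized_constricts_only_layer6(self, small_net, small_flow):
        pert = apply_scenario(small_net, ANESTHETIZED_AGED, small_flow)[0]
        layers = assign_layers(small_net)
        assert pert.regressed_vessels == []
        assert pert.scaled_vessels
        for vid, factor in pert.scaled_vessels.items():
            assert factor == 0.93
            assert layers[vid].label == "L6"

    def test_non_capillaries_never_touched(self, small_net, small_flow):
        pert = apply_scenario(small_net, AWAKE_AGED, small_flow, seeds=[0])[0]
        for vid, v in small_net.vessels.items():
            if v.type != "capillary":
                assert pert.network.vessels[vid].diameter == v.diameter

    def test_replicates_share_scaling_and_differ_in_regression(self, small_net, small_flow):
        reps = apply_scenario(small_net, RAREFACTION_ONLY, small_flow, seeds=[0, 1, 2])
        assert len(reps) == 3
        assert reps[0].scaled_vessels == reps[1].scaled_vessels == {}
        assert set(reps[0].regressed_vessels) != set(reps[1].regressed_vessels)
        assert len({len(r.regressed_vessels) for r in reps}) == 1

    def test_density_accounting_within_one_vessel(self, small_net, small_flow):
        layers = assign_layers(small_net)
        total6 = sum(
            1 for vid, v in small_net.vessels.items()
            if v.type == "capillary" and layers[vid].label == "L6"
        )
        pert = apply_scenario(small_net, RAREFACTION_ONLY, small_flow, seeds=[0])[0]
        target = RAREFACTION_ONLY.regression.target_density_fraction
        assert abs(len(pert.regressed_vessels) - target * total6) <= 1.0

    def test_regressed_flow_falls_below_low_percentile(self, small_net, small_flow):
        bc = build_boundary_conditions(small_net, "trimmed")
        pert = apply_scenario(small_net, RAREFACTION_ONLY, small_flow, seeds=[0])[0]
        fs2 = solve_flow(pert.network, bc, 0.3)
        all_q = np.array([abs(q) for q in fs2.flow.values()])
        mean_reg = np.mean([abs(fs2.flow[vid]) for vid in pert.regressed_vessels])
        assert mean_reg < np.percentile(all_q, 2.5)
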