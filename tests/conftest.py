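"""Shared fixtures: hand-built toy networks and scaled-down synthetic presets."""

from __future__ import annotations

import pytest

from mvnflow import GeneratorParams, VascularNetwork, generate_network
from mvnflow.network import NetworkNode, Vessel


def mknet(nodes, vessels, validate=True, name="toy") -> VascularNetwork:
    """Build a network from (id, x, y, z, is_boundary) and
    (id, node_a, node_b, diameter, length, type) tuples."""
    return VascularNetwork(
        [NetworkNode(*n) for n in nodes],
        [Vessel(*v) for v in vessels],
        name=name,
        validate=validate,
    )


@pytest.fixture
def y_net() -> VascularNetwork:
    """Arteriole feeding two capillaries that drain into one venule."""
    nodes = [
        ("in", 0.0, 0.0, 0.0, True),
        ("n1", 100.0, 0.0, 100.0, False),
        ("n2", 200.0, 0.0, 100.0, False),
        ("out", 300.0, 0.0, 0.0, True),
    ]
    vessels = [
        ("a1", "in", "n1", 12.0, 160.0, "pial_artery"),
        ("c1", "n1", "n2", 5.0, 120.0, "capillary"),
        ("c2", "n1", "n2", 5.0, 120.0, "capillary"),
        ("v1", "n2", "out", 12.0, 160.0, "pial_vein"),
    ]
    return mknet(nodes, vessels)


#: Desk-scale default (the MVN1-like configuration under test).
DEFAULT_SEED = 1

#: Reduced presets for fast tests.
SMALL_PARAMS = GeneratorParams(hex_cells=5, n_planes=6, n_arterioles=2, n_ascending_venules=2, n_pcv=1)
TINY_PARAMS = GeneratorParams(hex_cells=3, n_planes=4, n_arterioles=2, n_ascending_venules=1, n_pcv=1)


@pytest.fixture(scope="session")
def default_net() -> VascularNetwork:
    return generate_network(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def small_net() -> VascularNetwork:
    return generate_network(SMALL_PARAMS, seed=7)


@pytest.fixture(scope="session")
def tiny_net() -> VascularNetwork:
    return generate_network(TINY_PARAMS, seed=5)
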