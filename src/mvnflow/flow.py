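"""Steady-state Poiseuille flow on a vascular network.

The flow in each vessel obeys Poiseuille's law,

    q_ij = pi * D_ij^4 / (128 * L_ij * mu * mu_rel) * (p_i - p_j),

valid because the Reynolds number is small (< 1) throughout the
microvasculature. Mass conservation at every interior node yields a sparse
symmetric positive-definite linear system for the nodal pressures, solved
by direct sparse factorization.

Units: diameters/lengths in µm, pressures in mmHg (converted internally to
Pa), flows in µm³/s (1 µm³ = 1 fl), velocities in µm/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import ARTERIAL_TYPES, VENOUS_TYPES, VascularNetwork
from .rheology import (
    DEFAULT_RHEOLOGY,
    RheologyParams,
    relative_effective_viscosity,
    tube_hematocrit,
    velocity_factor,
)

MMHG_TO_PA = 133.322387415
#: Whole-blood density, kg/m³.
BLOOD_DENSITY_KG_M3 = 1050.0


class SolverError(RuntimeError):
    """Singular or anchorless pressure system."""


class ConfigurationError(ValueError):
    """Invalid boundary-condition configuration."""


@dataclass(frozen=True)
class PressureParams:
    """Boundary pressure assignment scheme (mmHg).

    Arterial boundaries get a high pressure, venous boundaries a low one,
    each attenuated linearly with depth toward the capillary midpoint so
    that deep cut vessels neither source nor sink unphysical flow. These
    values are configurable assumptions, not measurements.
    """

    arterial_surface_mmHg: float = 50.0
    venous_surface_mmHg: float = 10.0
    arterial_depth_drop_mmHg: float = 15.0
    venous_depth_rise_mmHg: float = 7.5
    reference_depth_um: float = 1000.0
    surface_z_um: float = 1.0  # nodes at z <= this count as pial surface

    def arterial(self, z: float) -> float:
        return self.arterial_surface_mmHg - self.arterial_depth_drop_mmHg * min(z / self.reference_depth_um, 1.0)

    def venous(self, z: float) -> float:
        return self.venous_surface_mmHg + self.venous_depth_rise_mmHg * min(z / self.reference_depth_um, 1.0)


@dataclass
class BoundaryConditions:
    """Per-boundary-node pressure/no-flow assignments.

    mode 'open': every boundary node carries a fixed pressure.
    mode 'trimmed': only pial-surface boundary nodes carry pressures; all
    subsurface boundaries are sealed (no flow crosses them).
    """

    mode: str
    fixed_pressure: dict[str, float] = field(default_factory=dict)  # node id -> mmHg
    no_flow: set[str] = field(default_factory=set)
    inflow_hematocrit: float = 0.3


def _boundary_side(net: VascularNetwork, node_id: str) -> str:
    """Classify a boundary node as arterial/venous/capillary by its vessels."""
    types = {v.type for v in net.incident_vessels(node_id)}
    if types & ARTERIAL_TYPES:
        return "arterial"
    if types & VENOUS_TYPES:
        return "venous"
    return "capillary"


def build_boundary_conditions(
    net: VascularNetwork,
    mode: str = "trimmed",
    pressure_params: PressureParams = PressureParams(),
    inflow_hematocrit: float = 0.3,
) -> BoundaryConditions:
    """Assign pressures (open) or pressures+seals (trimmed) to boundary nodes."""
    if mode not in ("open", "trimmed"):
        raise ConfigurationError(f"unknown boundary-condition mode {mode!r}")
    bc = BoundaryConditions(mode=mode, inflow_hematocrit=inflow_hematocrit)
    pp = pressure_params
    n_surface = 0
    for node in net.boundary_nodes():
        side = _boundary_side(net, node.id)
        at_surface = node.z <= pp.surface_z_um
        if at_surface:
            n_surface += 1
        if mode == "trimmed" and not at_surface:
            bc.no_flow.add(node.id)
            continue
        if side == "arterial":
            bc.fixed_pressure[node.id] = pp.arterial(node.z)
        elif side == "venous":
            bc.fixed_pressure[node.id] = pp.venous(node.z)
        else:
            bc.fixed_pressure[node.id] = 0.5 * (pp.arterial(node.z) + pp.venous(node.z))
    if mode == "trimmed" and n_surface == 0:
        raise ConfigurationError("trimmed mode requires at least one pial-surface boundary node")
    if not bc.fixed_pressure:
        raise ConfigurationError("no fixed-pressure boundary nodes assigned")
    return bc


@dataclass
class FlowState:
    """Solved pressure/flow field.

    flow is signed (positive node_a -> node_b). Hematocrits and RBC
    velocities are per-vessel; rbc_velocity is a magnitude (µm/s).
    """

    pressure: dict[str, float]  # node id -> mmHg
    flow: dict[str, float]  # vessel id -> µm³/s, signed a->b
    discharge_hct: dict[str, float]
    tube_hct: dict[str, float]
    rbc_velocity: dict[str, float]

    def bulk_velocity(self, net: VascularNetwork, vessel_id: str) -> float:
        v = net.vessels[vessel_id]
        return abs(self.flow[vessel_id]) / v.cross_section

    def to_frames(self, net: VascularNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
        vdf = pd.DataFrame(
            {
                "vessel_id": list(self.flow),
                "flow_um3_s": [self.flow[k] for k in self.flow],
                "tube_hct": [self.tube_hct[k] for k in self.flow],
                "discharge_hct": [self.discharge_hct[k] for k in self.flow],
                "rbc_velocity_um_s": [self.rbc_velocity[k] for k in self.flow],
            }
        )
        ndf = pd.DataFrame(
            {"node_id": list(self.pressure), "pressure_mmHg": [self.pressure[k] for k in self.pressure]}
        )
        return vdf, ndf

    def save_csv(self, net: VascularNetwork, vessel_path: str | Path, node_path: str | Path) -> None:
        vdf, ndf = self.to_frames(net)
        vdf.to_csv(vessel_path, index=False)
        ndf.to_csv(node_path, index=False)


def conductance(diameter_um: float, length_um: float, mu_mPas: float, mu_rel: float) -> float:
    """Poiseuille conductance in µm³ / (Pa·s)."""
    mu_pa_s = mu_mPas * 1e-3 * mu_rel
    g = math.pi * diameter_um**4 / (128.0 * length_um * mu_pa_s)
    if not math.isfinite(g) or g <= 0:
        raise ValueError(f"non-finite or non-positive conductance (D={diameter_um}, L={length_um})")
    return g


def solve_flow(
    net: VascularNetwork,
    bc: BoundaryConditions,
    hematocrit: Mapping[str, float] | float = 0.0,
    rheology: RheologyParams = DEFAULT_RHEOLOGY,
) -> FlowState:
    """Solve nodal pressures and vessel flows for a given hematocrit field.

    ``hematocrit`` is the discharge hematocrit per vessel id (or a scalar
    applied to every vessel); it sets the effective viscosity. The sealed
    (no-flow) boundary nodes of trimmed mode are simply unconstrained
    interior nodes of degree 1, which enforces zero flux naturally.
    """
    node_ids = list(net.nodes)
    idx = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)

    fixed = {nid: p for nid, p in bc.fixed_pressure.items() if nid in idx}
    if not fixed:
        raise SolverError("no fixed-pressure boundary node: pressure system has no anchor")

    def hd_of(vid: str) -> float:
        if isinstance(hematocrit, Mapping):
            return float(hematocrit.get(vid, 0.0))
        return float(hematocrit)

    g = {}
    for vid, v in net.vessels.items():
        mu_rel = relative_effective_viscosity(v.diameter, hd_of(vid), rheology)
        g[vid] = conductance(v.diameter, v.length, rheology.plasma_viscosity_mPas, mu_rel)

    # assemble Laplacian
    rows, cols, vals = [], [], []
    diag = np.zeros(n)
    for vid, v in net.vessels.items():
        i, j = idx[v.node_a], idx[v.node_b]
        gij = g[vid]
        diag[i] += gij
        diag[j] += gij
        rows += [i, j]
        cols += [j, i]
        vals += [-gij, -gij]
    lap = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    lap += sp.diags(diag)

    free = np.array([i for i, nid in enumerate(node_ids) if nid not in fixed], dtype=int)
    fixed_idx = np.array([idx[nid] for nid in fixed], dtype=int)
    p = np.zeros(n)
    p[fixed_idx] = np.array([fixed[nid] for nid in fixed]) * MMHG_TO_PA

    if free.size:
        a = lap[free][:, free].tocsc()
        b = -lap[free][:, fixed_idx] @ p[fixed_idx]
        # anchorless components make the reduced system singular
        try:
            sol = spla.spsolve(a, b)
        except Exception as exc:  # pragma: no cover - scipy raises various types
            raise SolverError(f"sparse solve failed: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise SolverError("singular pressure system (component without a pressure anchor)")
        p[free] = sol

    pressure = {nid: p[idx[nid]] / MMHG_TO_PA for nid in node_ids}
    flow, hd_map, ht_map, rbc_vel = {}, {}, {}, {}
    for vid, v in net.vessels.items():
        q = g[vid] * (p[idx[v.node_a]] - p[idx[v.node_b]])
        flow[vid] = q
        hd = hd_of(vid)
        hd_map[vid] = hd
        ht = tube_hematocrit(v.diameter, hd, rheology)
        ht_map[vid] = ht
        vf = velocity_factor(v.diameter, ht, rheology)
        rbc_vel[vid] = vf * abs(q) / v.cross_section
    return FlowState(pressure, flow, hd_map, ht_map, rbc_vel)


def node_residuals(net: VascularNetwork, flow: FlowState) -> dict[str, float]:
    """Net signed flow into each node (µm³/s); ~0 at interior nodes."""
    res = {nid: 0.0 for nid in net.nodes}
    for vid, v in net.vessels.items():
        q = flow.flow[vid]
        res[v.node_a] -= q
        res[v.node_b] += q
    return res


def reynolds_numbers(
    net: VascularNetwork,
    flow: FlowState,
    density_kg_m3: float = BLOOD_DENSITY_KG_M3,
    rheology: RheologyParams = DEFAULT_RHEOLOGY,
) -> dict[str, float]:
    """Per-vessel Reynolds number Re = rho * v * D / mu_eff (dimensionless)."""
    out = {}
    for vid, v in net.vessels.items():
        vel_m_s = flow.bulk_velocity(net, vid) * 1e-6
        d_m = v.diameter * 1e-6
        mu_eff = rheology.plasma_viscosity_mPas * 1e-3 * relative_effective_viscosity(
            v.diameter, flow.discharge_hct[vid], rheology
        )
        out[vid] = density_kg_m3 * vel_m_s * d_m / mu_eff
    return out
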