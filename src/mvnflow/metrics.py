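"""Per-vessel RBC metrics and layer-wise perfusion summaries.

Per vessel: RBC flux = |q| * htd / V_RBC (cells/s), RBC velocity
= vf * |q| / A (µm/s), and RBC linear density = flux / velocity
(cells per unit length). Layer summaries average these over the
analysis capillaries (depth within the 5th–95th percentile of all vessel
depths and at least two branches from any in/outflow), and the integral
capillary-bed inflow/outflow per layer is accumulated at the label
transition points where arterial vessels feed capillaries (start points)
and capillaries drain into venules (end points).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .flow import FlowState
from .network import (
    ARTERIAL_TYPES,
    LAYER_LABELS,
    VENOUS_TYPES,
    VascularNetwork,
    assign_layers,
    layer_of_depth,
    vessel_depth,
)
from .scenarios import EligibilityCriteria, _boundary_node_distances

__all__ = [
    "vessel_rbc_metrics",
    "analysis_capillaries",
    "layer_capillary_summary",
    "capillary_boundary_flows",
    "compare_states",
    "ComparisonError",
]

METRIC_COLUMNS = ("flux_cells_s", "velocity_um_s", "linear_density_cells_mm")


class ComparisonError(ValueError):
    """Baseline and perturbed summaries use different layer binnings."""


def vessel_rbc_metrics(flow: FlowState, net: VascularNetwork, v_rbc_fl: float = 49.0) -> pd.DataFrame:
    """Per-vessel RBC flux, velocity and linear density.

    Linear density is flux/velocity; vessels with zero RBC velocity get
    NaN density and are flagged (``density_undefined``), not dropped.
    """
    rows = []
    for vid, v in net.vessels.items():
        q = abs(flow.flow[vid])
        hd = flow.discharge_hct[vid]
        flux = q * hd / v_rbc_fl
        vel = flow.rbc_velocity[vid]
        if vel > 0:
            dens_mm = flux / vel * 1000.0
            flagged = False
        else:
            dens_mm = math.nan
            flagged = True
        rows.append((vid, flux, vel, dens_mm, flagged))
    return pd.DataFrame(
        rows, columns=["vessel_id", *METRIC_COLUMNS, "density_undefined"]
    ).set_index("vessel_id")


def analysis_capillaries(
    net: VascularNetwork,
    criteria: EligibilityCriteria = EligibilityCriteria(),
) -> set[str]:
    """Capillaries retained for layer averaging.

    Applies the two boundary-safety filters only (depth percentile window
    over all vessel depths, and at least two branches from any in/outflow);
    the trunk-distance thresholds select perturbation targets, not the
    analysis population.
    """
    depths_all = np.array([vessel_depth(v, net) for v in net.vessels.values()])
    lo = np.percentile(depths_all, criteria.depth_pct_low)
    hi = np.percentile(depths_all, criteria.depth_pct_high)
    node_dist = _boundary_node_distances(net)
    out = set()
    for vid, v in net.vessels.items():
        if v.type != "capillary":
            continue
        if not lo <= vessel_depth(v, net) <= hi:
            continue
        if min(node_dist[v.node_a], node_dist[v.node_b]) < criteria.min_branches_from_boundary:
            continue
        out.add(vid)
    return out


def layer_capillary_summary(
    net: VascularNetwork,
    flow: FlowState,
    capillary_filter: set[str] | None = None,
    v_rbc_fl: float = 49.0,
) -> pd.DataFrame:
    """Mean and median RBC metrics per cortical layer over filtered capillaries.

    Layers left empty by the filter appear as rows with n=0 and NaN
    statistics. Also reports the integral capillary-bed inflow/outflow
    per layer (µm³/s).
    """
    if capillary_filter is None:
        capillary_filter = analysis_capillaries(net)
    metrics = vessel_rbc_metrics(flow, net, v_rbc_fl)
    layers = assign_layers(net)
    boundary_flows = capillary_boundary_flows(net, flow)
    rows = []
    for label in LAYER_LABELS:
        vids = [vid for vid in capillary_filter if layers[vid].label == label]
        sub = metrics.loc[vids] if vids else metrics.iloc[0:0]
        row = {"layer": label, "n_capillaries": len(vids)}
        for col in METRIC_COLUMNS:
            vals = sub[col].dropna()
            row[f"mean_{col}"] = float(vals.mean()) if len(vals) else math.nan
            row[f"median_{col}"] = float(vals.median()) if len(vals) else math.nan
        row["capillary_inflow_um3_s"] = boundary_flows.loc[label, "inflow_um3_s"]
        row["capillary_outflow_um3_s"] = boundary_flows.loc[label, "outflow_um3_s"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("layer")


def capillary_boundary_flows(net: VascularNetwork, flow: FlowState) -> pd.DataFrame:
    """Integral capillary-bed inflow/outflow per layer (µm³/s).

    A capillary start point is a node where the vessel label changes from
    an arterial type to capillary; an end point where capillary changes
    to a venous type. The arterial flow entering each start point (and
    venous flow leaving each end point) is summed per layer, binned by
    the depth of the transition node.
    """
    inflow = {label: 0.0 for label in LAYER_LABELS}
    outflow = {label: 0.0 for label in LAYER_LABELS}
    for nid, node in net.nodes.items():
        incident = net.incident_vessels(nid)
        types = {v.type for v in incident}
        if "capillary" not in types:
            continue
        label = layer_of_depth(node.z).label

        def signed_into_node(v) -> float:
            q = flow.flow[v.id]
            return q if v.node_b == nid else -q

        if types & ARTERIAL_TYPES:
            for v in incident:
                if v.type in ARTERIAL_TYPES:
                    inflow[label] += max(signed_into_node(v), 0.0)
        if types & VENOUS_TYPES:
            for v in incident:
                if v.type in VENOUS_TYPES:
                    outflow[label] += max(-signed_into_node(v), 0.0)
    return pd.DataFrame(
        {
            "inflow_um3_s": [inflow[label] for label in LAYER_LABELS],
            "outflow_um3_s": [outflow[label] for label in LAYER_LABELS],
        },
        index=pd.Index(LAYER_LABELS, name="layer"),
    )


def compare_states(baseline: pd.DataFrame, perturbed: list[pd.DataFrame]) -> pd.DataFrame:
    """Tidy change table: baseline vs replicate median ± s.d. per layer and metric.

    Percent change is 100 * (perturbed_median - baseline) / baseline.
    Replicate aggregation is the median with the s.d. as spread; the mean
    is also emitted.
    """
    if not perturbed:
        raise ComparisonError("no perturbed summaries supplied")
    for p in perturbed:
        if list(p.index) != list(baseline.index):
            raise ComparisonError("layer binning differs between baseline and perturbed summaries")
    value_cols = [c for c in baseline.columns if c.startswith(("mean_", "median_"))] + [
        "capillary_inflow_um3_s",
        "capillary_outflow_um3_s",
    ]
    rows = []
    for layer in baseline.index:
        for col in value_cols:
            base = baseline.loc[layer, col]
            vals = np.array([p.loc[layer, col] for p in perturbed], dtype=float)
            med = float(np.median(vals))
            rows.append(
                {
                    "layer": layer,
                    "metric": col,
                    "baseline": base,
                    "perturbed_median": med,
                    "perturbed_mean": float(np.mean(vals)),
                    "perturbed_sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                    "change": med - base,
                    "pct_change": 100.0 * (med - base) / base if base not in (0.0,) and not math.isnan(base) else math.nan,
                }
            )
    return pd.DataFrame(rows)
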