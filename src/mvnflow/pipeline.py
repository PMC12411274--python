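"""Experiment orchestration: generate -> simulate -> perturb -> re-simulate -> compare.

An experiment runs, for each boundary-condition mode, a baseline
time-averaged simulation and then every configured aging scenario
(regression scenarios over several random-replicate draws), writing flow
fields, layer summaries, change tables and a provenance JSON to the
output directory. All stage seeds derive from one master seed through a
stable keyed scheme, so adding scenarios or modes never changes the
randomness of earlier stages.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .flow import PressureParams, build_boundary_conditions
from .metrics import compare_states, layer_capillary_summary
from .network import VascularNetwork, load_network, save_network
from .rbc import SimulationParams, simulate_time_average
from .rheology import DEFAULT_RHEOLOGY, RheologyParams
from .scenarios import NAMED_SCENARIOS, Scenario, apply_scenario
from .synthetic import GeneratorParams, generate_network

log = logging.getLogger("mvnflow")


def derive_seed(master_seed: int, *key: object) -> int:
    """Stable per-stage seed below 2^31, keyed by stage identity."""
    text = ":".join([str(master_seed), *map(str, key)])
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


@dataclass
class ExperimentConfig:
    """Full experiment description (normally loaded from YAML)."""

    network_path: str | None = None  # directory with nodes.csv/vessels.csv
    generator: GeneratorParams | None = None
    bc_modes: list[str] = field(default_factory=lambda: ["open", "trimmed"])
    scenarios: list[str] = field(default_factory=lambda: ["anesthetized_aged", "awake_aged"])
    pressure: PressureParams = field(default_factory=PressureParams)
    rheology: RheologyParams = field(default_factory=lambda: DEFAULT_RHEOLOGY)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    out_dir: str = "experiment_out"
    master_seed: int = 0

    def validate(self) -> None:
        if not self.bc_modes:
            raise ValueError("at least one boundary-condition mode is required")
        for m in self.bc_modes:
            if m not in ("open", "trimmed"):
                raise ValueError(f"unknown BC mode {m!r}")
        for s in self.scenarios:
            if s not in NAMED_SCENARIOS:
                raise ValueError(f"unknown scenario {s!r} (known: {sorted(NAMED_SCENARIOS)})")
        if self.network_path is not None and not Path(self.network_path).exists():
            raise ValueError(f"network path {self.network_path!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("network_path", "out_dir", "master_seed", "bc_modes", "scenarios"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "generator" in raw:
            cfg.generator = GeneratorParams(**raw["generator"])
        if "pressure" in raw:
            cfg.pressure = PressureParams(**raw["pressure"])
        if "rheology" in raw:
            cfg.rheology = RheologyParams(**raw["rheology"])
        if "simulation" in raw:
            cfg.simulation = SimulationParams(**raw["simulation"])
        return cfg


def _get_network(cfg: ExperimentConfig) -> VascularNetwork:
    if cfg.network_path is not None:
        p = Path(cfg.network_path)
        return load_network(p / "nodes.csv", p / "vessels.csv")
    params = cfg.generator or GeneratorParams()
    return generate_network(params, seed=derive_seed(cfg.master_seed, "generate"))


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the full pipeline; returns a manifest of written artifacts."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = _get_network(cfg)
    save_network(net, out / "nodes.csv", out / "vessels.csv")
    manifest: dict = {"network": net.name, "n_vessels": len(net.vessels), "outputs": []}

    for mode in cfg.bc_modes:
        bc = build_boundary_conditions(net, mode, cfg.pressure)
        sim_params = dataclasses.replace(cfg.simulation, seed=derive_seed(cfg.master_seed, mode, "baseline"))
        log.info("baseline simulation: mode=%s seed=%d", mode, sim_params.seed)
        baseline = simulate_time_average(net, bc, cfg.rheology, sim_params)
        log.info(
            "baseline %s: window=%.2fs coverage=%.1f%%", mode,
            baseline.averaging_window_s, 100 * baseline.coverage,
        )
        tag = f"{mode}_baseline"
        baseline.save_csv(net, out / f"{tag}_vessels.csv", out / f"{tag}_nodes.csv")
        base_summary = layer_capillary_summary(net, baseline)
        base_summary.to_csv(out / f"{tag}_layers.csv")
        manifest["outputs"].append(tag)

        for scen_name in cfg.scenarios:
            scenario = NAMED_SCENARIOS[scen_name]
            n_rep = scenario.regression.n_replicates if scenario.regression else 1
            rep_seeds = [derive_seed(cfg.master_seed, mode, scen_name, r) for r in range(n_rep)]
            perturbed = apply_scenario(net, scenario, baseline,
                                       seeds=rep_seeds if scenario.regression else None)
            summaries = []
            for rep, pert in enumerate(perturbed):
                sp = dataclasses.replace(
                    cfg.simulation, seed=derive_seed(cfg.master_seed, mode, scen_name, rep, "sim")
                )
                taf = simulate_time_average(pert.network, bc, cfg.rheology, sp)
                log.info(
                    "%s/%s rep %d: window=%.2fs coverage=%.1f%%", mode, scen_name, rep,
                    taf.averaging_window_s, 100 * taf.coverage,
                )
                rtag = f"{mode}_{scen_name}_rep{rep}"
                taf.save_csv(pert.network, out / f"{rtag}_vessels.csv", out / f"{rtag}_nodes.csv")
                summaries.append(layer_capillary_summary(pert.network, taf))
                manifest["outputs"].append(rtag)
            table = compare_states(base_summary, summaries)
            table.to_csv(out / f"{mode}_{scen_name}_changes.csv", index=False)
            manifest["outputs"].append(f"{mode}_{scen_name}_changes")

    provenance = {
        "version": __version__,
        "master_seed": cfg.master_seed,
        "config": {
            "network_path": cfg.network_path,
            "generator": dataclasses.asdict(cfg.generator) if cfg.generator else None,
            "bc_modes": cfg.bc_modes,
            "scenarios": cfg.scenarios,
            "pressure": dataclasses.asdict(cfg.pressure),
            "rheology": dataclasses.asdict(cfg.rheology),
            "simulation": dataclasses.asdict(cfg.simulation),
        },
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1))
    manifest["provenance"] = str(out / "provenance.json")
    return manifest
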