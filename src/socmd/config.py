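"""Structured text (YAML) configuration for machine, workload and runs.

Example::

    machine:
      pipeline_efficiency: 0.30
      gp_efficiency: 0.20
    workload:
      total_atoms: 50000
      atoms_per_node: 100
    simulation:
      dt: 0.004
      n_steps: 500
      cutoff: 2.5
      kernel: gaussian
      alpha: 0.0

Any omitted key falls back to the package default.
"""

from __future__ import annotations

import yaml

from .engine import SimulationConfig
from .perf import MachineSpec, WorkloadSpec
from .pipeline import PipelineConfig
from .torus import LinkSpec, LatencyModel

__all__ = ["load_config", "machine_from_dict", "workload_from_dict",
           "simulation_from_dict"]


def machine_from_dict(d: dict) -> MachineSpec:
    d = dict(d or {})
    if "link" in d:
        d["link"] = LinkSpec(**d["link"])
    if "latency" in d:
        lat = d["latency"]
        d["latency"] = LatencyModel(
            base_ns=lat.get("base_ns", 600.0),
            per_hop_ns=lat.get("per_hop_ns", 450.0),
            per_128_words_ns=lat.get("per_128_words_ns", 200.0))
    return MachineSpec(**d)


def workload_from_dict(d: dict) -> WorkloadSpec:
    d = dict(d or {})
    if "mesh_dims" in d:
        d["mesh_dims"] = tuple(d["mesh_dims"])
    return WorkloadSpec(**d)


def simulation_from_dict(d: dict) -> SimulationConfig:
    d = dict(d or {})
    pipe_keys = {"alpha", "kernel", "combination_rule_sigma",
                 "combination_rule_epsilon", "cutoff_radius"}
    pipe = {k: d.pop(k) for k in list(d) if k in pipe_keys}
    if "cutoff" in d and "cutoff_radius" not in pipe:
        pipe["cutoff_radius"] = d["cutoff"]
    config = SimulationConfig(**d)
    if pipe:
        config.pipeline = PipelineConfig(**{
            **{k: getattr(config.pipeline, k) for k in (
                "alpha", "kernel", "combination_rule_sigma",
                "combination_rule_epsilon", "cutoff_radius", "softcore",
                "group_exclusions", "exclude_same_group", "force_fmt")},
            **pipe})
    return config


def load_config(path):
    """Load a YAML config file into (machine, workload, simulation)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return (machine_from_dict(raw.get("machine", {})),
            workload_from_dict(raw.get("workload", {})),
            simulation_from_dict(raw.get("simulation", {})))
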