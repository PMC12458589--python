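"""Structured YAML configuration covering every model parameter.

One YAML file mirrors the full parameter surface: the run definition
(``sim:``), DBS (``dbs:``), noise (``noise:``), RNG seeds (``seeds:``),
the microcircuit (``micro:``), the regional ionic tables (``regions:``,
including each region's gate kinetics), the inter-nucleus connections
(``connections:``), the SMC pulse train (``smc:``), and the synthetic
connectome (``connectome:``).  :func:`default_config_dict` documents the
shipped defaults; :func:`load_config` merges a user file over them, so a
config file only needs the keys it overrides.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .connectome import synth_connectome
from .engine import NoiseParams, Seeds, SimConfig
from .errors import FormatError
from .microcircuit import MicroParams
from .regions import (
    BGTHParams,
    GateKinetics,
    RegionParams,
    SMCParams,
    SynapseParams,
)
from .stimulation import DBSParams


def config_to_dict(sim: SimConfig, params: BGTHParams,
                   micro: MicroParams, connectome_spec: dict | None = None) -> dict:
    """Flatten the full configuration into plain nested dicts."""
    d = {
        "sim": {
            "dt": sim.dt,
            "duration": sim.duration,
            "pd": sim.pd,
            "n_micro": sim.n_micro,
            "record_stride": sim.record_stride,
            "record_rasters": sim.record_rasters,
            "record_currents": sim.record_currents,
        },
        "dbs": {**asdict(sim.dbs), "targets": list(sim.dbs.targets)},
        "noise": {**asdict(sim.noise), "sigma": list(sim.noise.sigma)},
        "seeds": asdict(sim.seeds),
        "micro": asdict(micro),
        "regions": {name: asdict(rp) for name, rp in params.regions.items()},
        "connections": {name: asdict(sp) for name, sp in params.synapses.items()},
        "smc": asdict(params.smc),
        "connectome": connectome_spec
        or {"n_nodes": 4, "density": 1.0, "seed": 7, "rho": 1.0},
    }
    return d


def default_config_dict() -> dict:
    """The shipped default configuration as plain dicts."""
    return config_to_dict(SimConfig(), BGTHParams(), MicroParams())


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def config_from_dict(d: dict):
    """Rebuild ``(SimConfig, BGTHParams, MicroParams, connectome_spec)``.

    Missing keys fall back to the shipped defaults.
    """
    d = _merge(default_config_dict(), d or {})
    try:
        sim = SimConfig(
            **d["sim"],
            dbs=DBSParams(**d["dbs"]),
            noise=NoiseParams(**d["noise"]),
            seeds=Seeds(**d["seeds"]),
        )
        micro = MicroParams(**d["micro"])
        regions = {}
        for name, rp in d["regions"].items():
            gates = {g: GateKinetics(**kin) for g, kin in rp.pop("gates", {}).items()}
            regions[name] = RegionParams(**rp, gates=gates)
        synapses = {name: SynapseParams(**sp)
                    for name, sp in d["connections"].items()}
        params = BGTHParams(regions=regions, synapses=synapses,
                            smc=SMCParams(**d["smc"]))
    except TypeError as err:
        raise FormatError(f"malformed configuration: {err}") from err
    sim.validate()
    params.validate()
    micro.validate()
    return sim, params, micro, d["connectome"]


def load_config(path):
    """Load a YAML config file (merged over the shipped defaults)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise FormatError(f"config file {path} must contain a mapping")
    return config_from_dict(data)


def save_config(path, sim: SimConfig = None, params: BGTHParams = None,
                micro: MicroParams = None, connectome_spec: dict = None) -> None:
    """Write a full configuration (defaults where arguments are None)."""
    d = config_to_dict(
        sim or SimConfig(), params or BGTHParams(), micro or MicroParams(),
        connectome_spec,
    )
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def connectome_from_spec(spec: dict):
    """Build the synthetic connectome described by a ``connectome:`` block."""
    return synth_connectome(
        n_nodes=int(spec.get("n_nodes", 4)),
        density=float(spec.get("density", 1.0)),
        seed=spec.get("seed", 7),
        rho=float(spec.get("rho", 1.0)),
    )
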