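"""YAML configuration files describing an ecology and its simulation settings.

Schema (version 1)::

    schema: 1
    chemicals:
      growth_values: [1.0, 1.0, 0.5, 0.5]
      dilution_rate: 0.1
      feeds:
        - {kind: constant, level: 200}
        - {kind: sine, low: 40, high: 200, period: 2.5e4, phase_deg: 180}
        - {kind: constant, level: 0}
        - {kind: constant, level: 0}
    simulation: {g: 0.05, e_div: 100, ...}      # any SimulationConfig field
    types:
      - type_id: 0
        diet: [0, 1]
        byproducts: [2, 3]
        weights: [[0.4, 0.0], [0.0, 0.4]]
        enzymes: [30, 30]
        enzyme_costs: [0.1, 0.1]
        budget_weights: [1, 1]
        maintenance: 10
        e_budget: 60
        reg_enabled: true
        regulation: null            # null => fresh disabled network when reg_enabled
        initial_count: 100

Validation is strict: every problem is reported with the key path that caused
it.  Round-tripping a configuration through a file is the identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
import yaml

from .core import (ChemicalSystem, Ecology, FeedChannel, FeedSchedule,
                   ProtocrmError, SimulationConfig)
from .regulation import RegulatoryNetwork
from .serialize import network_to_dict, type_from_dict, type_to_dict

__all__ = ["ConfigError", "load_config", "save_config", "parse_config",
           "dump_config", "config_hash"]


class ConfigError(ProtocrmError):
    """Invalid configuration file; message carries the offending key path."""


def _need(mapping: dict, key: str, path: str):
    if key not in mapping:
        raise ConfigError(f"{path}.{key}: missing required key")
    return mapping[key]


def _feed_channel(data: dict, path: str) -> FeedChannel:
    kind = data.get("kind", "constant")
    try:
        if kind == "constant":
            return FeedChannel("constant", level=float(data.get("level", 0.0)))
        if kind == "sine":
            return FeedChannel(
                "sine", low=float(_need(data, "low", path)),
                high=float(_need(data, "high", path)),
                period=float(_need(data, "period", path)),
                phase_deg=float(data.get("phase_deg", 0.0)),
            )
    except ProtocrmError as exc:
        raise ConfigError(f"{path}: {exc}") from exc
    raise ConfigError(f"{path}.kind: unknown feed kind {kind!r}")


def parse_config(data: dict):
    """Build ``(ecology, simulation_config)`` from a parsed mapping."""
    if not isinstance(data, dict):
        raise ConfigError("top level: expected a mapping")
    if data.get("schema", 1) != 1:
        raise ConfigError(f"schema: unsupported version {data.get('schema')!r}")

    chem_data = _need(data, "chemicals", "top level")
    gv = _need(chem_data, "growth_values", "chemicals")
    feeds_data = _need(chem_data, "feeds", "chemicals")
    if len(feeds_data) != len(gv):
        raise ConfigError(
            f"chemicals.feeds: {len(feeds_data)} channels for {len(gv)} chemicals")
    feed = FeedSchedule(tuple(
        _feed_channel(ch, f"chemicals.feeds[{k}]")
        for k, ch in enumerate(feeds_data)
    ))
    try:
        chem = ChemicalSystem(np.asarray(gv, float), feed,
                              float(_need(chem_data, "dilution_rate", "chemicals")))
    except ProtocrmError as exc:
        raise ConfigError(f"chemicals: {exc}") from exc

    sim_data = dict(data.get("simulation", {}))
    valid_fields = {f.name for f in dataclasses.fields(SimulationConfig)}
    for key in sim_data:
        if key not in valid_fields:
            raise ConfigError(f"simulation.{key}: unknown parameter")
    try:
        cfg = SimulationConfig(**sim_data)
    except (ProtocrmError, TypeError) as exc:
        raise ConfigError(f"simulation: {exc}") from exc

    types = []
    counts = []
    for k, tdata in enumerate(_need(data, "types", "top level")):
        path = f"types[{k}]"
        tdata = dict(tdata)
        counts.append(int(tdata.pop("initial_count", 100)))
        tdata.setdefault("e_budget", cfg.e_budget)
        tdata.setdefault("type_id", k)
        reg_enabled = bool(tdata.get("reg_enabled", False))
        if reg_enabled and tdata.get("regulation") is None:
            tdata["regulation"] = network_to_dict(
                RegulatoryNetwork.disabled(len(_need(tdata, "diet", path)),
                                           k_tau=cfg.k_tau))
        try:
            types.append(type_from_dict(tdata))
        except (ProtocrmError, KeyError, ValueError) as exc:
            raise ConfigError(f"{path}: {exc}") from exc

    try:
        ecology = Ecology(chem, types, initial_counts=counts)
    except ProtocrmError as exc:
        raise ConfigError(f"types: {exc}") from exc
    return ecology, cfg


def load_config(path):
    """Parse a YAML config file into ``(ecology, simulation_config)``."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: YAML parse error: {exc}") from exc
    return parse_config(data)


def dump_config(ecology: Ecology, cfg: SimulationConfig) -> dict:
    channels = []
    for ch in ecology.chemicals.feed.channels:
        if ch.kind == "constant":
            channels.append({"kind": "constant", "level": ch.level})
        else:
            channels.append({"kind": "sine", "low": ch.low, "high": ch.high,
                             "period": ch.period, "phase_deg": ch.phase_deg})
    types = []
    for t, n0 in zip(ecology.types, ecology.initial_counts):
        d = type_to_dict(t)
        d["initial_count"] = int(n0)
        types.append(d)
    return {
        "schema": 1,
        "chemicals": {
            "growth_values": ecology.chemicals.growth_values.tolist(),
            "dilution_rate": ecology.chemicals.dilution_rate,
            "feeds": channels,
        },
        "simulation": dataclasses.asdict(cfg),
        "types": types,
    }


def save_config(ecology: Ecology, cfg: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dump_config(ecology, cfg), fh, sort_keys=False)


def config_hash(ecology: Ecology, cfg: SimulationConfig) -> str:
    """Stable short hash of the full resolved configuration (provenance)."""
    blob = json.dumps(dump_config(ecology, cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
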