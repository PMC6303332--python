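"""Declarative YAML run configuration.

A run config describes a full battery (panel, population, matrices,
phenotypes, models, replicates, seed) as nested mappings mirroring the
recipe dataclasses.  Unknown keys are rejected, every seed is explicit, and
a stable content hash is provided for provenance logs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import yaml

from .experiments import ExperimentConfig, PanelRecipe, PopulationRecipe

__all__ = ["load_config", "parse_config", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    """Raised for malformed run configurations."""


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys {sorted(unknown)} in {path}")
    return data


def parse_config(data: dict) -> ExperimentConfig:
    """Validate a nested mapping and build an :class:`ExperimentConfig`."""
    if not isinstance(data, dict):
        raise ConfigError("run config must be a mapping")
    data = dict(data)
    panel = PanelRecipe(**_build(PanelRecipe, data.pop("panel", {}), "panel"))
    pop = PopulationRecipe(
        **_build(PopulationRecipe, data.pop("population", {}), "population"))
    for listy in ("M_grid", "models"):
        if listy in data:
            data[listy] = tuple(data[listy])
    fields = _build(ExperimentConfig, data, "top level")
    try:
        return ExperimentConfig(population=pop, panel=panel, **fields)
    except (TypeError, ValueError) as err:
        raise ConfigError(str(err)) from err


def load_config(path: str) -> ExperimentConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return parse_config(data)


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of a config's content (for provenance logs)."""
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True,
                      default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
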