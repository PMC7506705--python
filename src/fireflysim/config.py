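"""Configuration: strict YAML loading of instrument and tool settings.

Every instrument coefficient is addressable by the name used in its type
definition; unknown keys are rejected with an explicit error so typos can
never silently fall back to defaults.  The shipped defaults live in
``data/instrument_defaults.yaml``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Dict, Optional

import yaml

from .exceptions import ConfigError
from .instrument import (BandGrid, DarkModel, FwhmSurface, InstrumentModel,
                         NoiseModel, ResponseModel)

__all__ = ["build_instrument", "load_instrument_yaml", "default_instrument",
           "ToolConfig", "load_tool_config", "config_hash"]

_INSTRUMENT_SECTIONS = {
    "band_grid": ("grid", BandGrid),
    "fwhm": ("fwhm", FwhmSurface),
    "response": ("response", ResponseModel),
    "noise": ("noise", NoiseModel),
    "dark": ("dark", DarkModel),
}


def _check_keys(mapping: Dict[str, Any], allowed, context: str) -> None:
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in {context}; "
            f"allowed: {sorted(allowed)}")


def build_instrument(mapping: Dict[str, Any]) -> InstrumentModel:
    """Build an InstrumentModel from a nested mapping; unknown keys raise."""
    _check_keys(mapping, _INSTRUMENT_SECTIONS, "instrument config")
    kwargs = {}
    for section, (attr, cls) in _INSTRUMENT_SECTIONS.items():
        sub = mapping.get(section, {}) or {}
        names = {f.name for f in dataclasses.fields(cls)}
        _check_keys(sub, names, f"instrument.{section}")
        kwargs[attr] = cls(**sub)
    return InstrumentModel(**kwargs)


def load_instrument_yaml(path) -> InstrumentModel:
    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return build_instrument(mapping.get("instrument", mapping))


def default_instrument() -> InstrumentModel:
    """Instrument built from the shipped, versioned defaults file."""
    ref = resources.files("fireflysim").joinpath(
        "data/instrument_defaults.yaml")
    mapping = yaml.safe_load(ref.read_text())
    return build_instrument(mapping["instrument"])


_TOOL_KEYS = {"instrument", "scene", "retrieval", "run"}
_SCENE_KEYS = {"n_vegetation", "panels", "seed", "noise_on"}
_RETRIEVAL_KEYS = {"method", "ndvi_red", "ndvi_nir", "weighted"}
_RUN_KEYS = {"seed", "output_dir", "log_level"}


@dataclasses.dataclass(frozen=True)
class ToolConfig:
    """Top-level tool configuration (CLI surface)."""

    instrument: InstrumentModel
    scene: Dict[str, Any]
    retrieval: Dict[str, Any]
    run: Dict[str, Any]
    raw: Dict[str, Any]


def load_tool_config(path: Optional[str] = None) -> ToolConfig:
    """Load a tool config YAML; omitted sections fall back to defaults."""
    raw: Dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        _check_keys(raw, _TOOL_KEYS, "tool config")
    scene = dict(raw.get("scene", {}) or {})
    _check_keys(scene, _SCENE_KEYS, "scene config")
    retrieval = dict(raw.get("retrieval", {}) or {})
    _check_keys(retrieval, _RETRIEVAL_KEYS, "retrieval config")
    run = dict(raw.get("run", {}) or {})
    _check_keys(run, _RUN_KEYS, "run config")
    instrument = build_instrument(raw.get("instrument", {}) or {})
    return ToolConfig(instrument=instrument, scene=scene,
                      retrieval=retrieval, run=run, raw=raw)


def config_hash(config: ToolConfig) -> str:
    """Stable short hash of the raw configuration (for run logs)."""
    blob = json.dumps(config.raw, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
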