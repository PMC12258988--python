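"""Flat YAML/JSON configuration loading for parameters and current programs."""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .model import ModelParameters, ParameterError
from .protocols import CurrentProgram

__all__ = ["load_config", "parse_overrides", "dump_config"]

_PARAM_KEYS = {f.name for f in fields(ModelParameters)} | {"g_Kv1.2"}


def parse_overrides(pairs) -> dict:
    """Parse ``key=value`` strings (CLI ``--set``) into parameter overrides."""
    out = {}
    for pair in pairs:
        if "=" not in pair:
            raise ParameterError(f"override {pair!r} is not of the form key=value")
        key, _, raw = pair.partition("=")
        key = key.strip()
        if key not in _PARAM_KEYS:
            raise ParameterError(f"unknown parameter key {key!r}")
        out[key] = float(raw)
    return out


def load_config(path) -> tuple:
    """Load a flat key-value config file.

    Parameter keys are the :class:`ModelParameters` field names (plus the
    literature spelling ``g_Kv1.2``); an optional ``program`` key holds a
    list of segment mappings (duration / kind / start_value / end_value).
    Unknown keys are rejected with an error naming the key.  An empty file
    yields the full defaults.

    Returns ``(params, program_or_None)``.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ParameterError(f"config {path} must be a mapping, got {type(data)}")
    program_spec = data.pop("program", None)
    unknown = set(data) - _PARAM_KEYS
    if unknown:
        raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
    params = ModelParameters.from_dict(data)
    program = CurrentProgram.from_spec(program_spec) if program_spec else None
    return params, program


def dump_config(params: ModelParameters, path, program=None) -> None:
    data = params.to_dict()
    if program is not None:
        data["program"] = program.to_spec()
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
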