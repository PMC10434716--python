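"""Configuration, serialization, and reproducibility plumbing.

The default parameter set ships as a nested YAML file inside the package;
user configs override individual keys and unknown keys are rejected with the
offending key path.  Every run can be captured in a :class:`RunManifest`
sufficient to re-execute it bit-identically with the same code version.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .field_core import FieldParams, InvalidParameterError

__all__ = [
    "ConfigError",
    "RunManifest",
    "load_config",
    "default_params",
    "params_hash",
    "write_table",
    "read_table",
]

#: Nested config sections and the flat FieldParams key each entry maps to.
_SECTIONS = {
    "field": (
        "tau_u", "tau_v", "h_u", "h_v", "beta",
        "w_uu_amp", "w_uu_width", "w_uv_amp", "w_uv_width",
        "w_vu_amp", "w_vu_width", "input_width",
    ),
    "trace": (
        "trace_build_tau", "trace_decay_tau", "trace_gain",
        "trace_spread_width",
    ),
    "adaptation": ("adapt_tau", "adapt_gain"),
    "noise": ("noise_slow_tau", "noise_slow_amp", "noise_fast_amp"),
    "integration": ("dt",),
}


class ConfigError(ValueError):
    """Schema violation in a configuration file."""


def _flatten(nested: dict) -> dict:
    flat = {}
    for section, entries in nested.items():
        if section not in _SECTIONS:
            raise ConfigError(f"unknown config section '{section}'")
        if not isinstance(entries, dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        for key, value in entries.items():
            if key not in _SECTIONS[section]:
                raise ConfigError(f"unknown config key '{section}.{key}'")
            flat[key] = value
    return flat


def _nest(params: FieldParams) -> dict:
    d = params.to_dict()
    return {
        section: {key: d[key] for key in keys}
        for section, keys in _SECTIONS.items()
    }


def default_params() -> FieldParams:
    """The calibrated single parameter set shipped with the package."""
    text = (
        resources.files("visfield") / "config" / "default_params.yaml"
    ).read_text()
    return FieldParams.from_dict(_flatten(yaml.safe_load(text)))


def load_config(path: str | Path | None = None) -> FieldParams:
    """Defaults merged with overrides from a nested YAML file.

    An empty or missing-override file returns the defaults; unknown keys and
    invalid values raise :class:`ConfigError` naming the key path.
    """
    params = default_params().to_dict()
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        overrides = yaml.safe_load(p.read_text()) or {}
        if not isinstance(overrides, dict):
            raise ConfigError("config root must be a mapping of sections")
        params.update(_flatten(overrides))
    try:
        return FieldParams.from_dict(params)
    except InvalidParameterError as exc:
        raise ConfigError(str(exc)) from exc


def params_hash(params: FieldParams) -> str:
    """Hash of the canonical parameter serialization (single-set contract)."""
    canon = json.dumps(params.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_table(rows, path: str | Path) -> Path:
    """Comma-separated table with header; lossless numeric round-trip."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    master_seed: int
    params: FieldParams
    outputs: list = dc_field(default_factory=list)
    code_version: str = "0.1.0"
    timestamp: str = dc_field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "master_seed": self.master_seed,
            "params": _nest(self.params),
            "params_hash": params_hash(self.params),
            "outputs": [str(o) for o in self.outputs],
            "code_version": self.code_version,
            "timestamp": self.timestamp,
        }
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
        return path
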