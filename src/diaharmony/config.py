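"""Study configuration loading: method constants, sample design, QC bounds.

The packaged ``data/default_config.yaml`` holds the documented full-scale
defaults; user YAML/JSON files override any subset of its sections.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dia_method import DIAMethod, build_window_scheme
from .errors import ConfigError

__all__ = [
    "default_config",
    "load_config",
    "method_from_config",
    "merge_config",
]


def default_config() -> dict[str, Any]:
    """Deep copy of the packaged default configuration."""
    text = (
        resources.files("diaharmony").joinpath("data/default_config.yaml").read_text()
    )
    return yaml.safe_load(text)


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load a study config, overlaying user settings on the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    path = Path(path)
    raw = path.read_text()
    user = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if user is None:
        return cfg
    if not isinstance(user, Mapping):
        raise ConfigError(f"config root must be a mapping, got {type(user).__name__}")
    return merge_config(cfg, user)


def merge_config(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    """Recursively merge ``override`` into ``base`` (override wins)."""
    merged = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(merged.get(key), Mapping):
            merged[key] = merge_config(merged[key], value)
        else:
            merged[key] = value
    return merged


def method_from_config(cfg: Mapping[str, Any] | None = None) -> DIAMethod:
    """Build the acquisition method from a config's ``dia_method`` block."""
    cfg = cfg if cfg is not None else default_config()
    block = cfg.get("dia_method")
    if block is None:
        raise ConfigError("config lacks a 'dia_method' section")
    try:
        return build_window_scheme(
            mz_start=float(block["mz_start"]),
            mz_end=float(block["mz_end"]),
            window_width=float(block["window_width"]),
            scans_per_subcycle=int(block["scans_per_subcycle"]),
            ms1_cycle_time=float(block["ms1_cycle_time"]),
            ms2_cycle_time=float(block["ms2_cycle_time"]),
        )
    except KeyError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"dia_method section missing key {exc}") from exc
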