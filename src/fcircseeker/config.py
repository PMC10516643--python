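"""Run configuration: defaults < config file < explicit overrides.

A :class:`RunConfig` bundles the simulator, detector, filter, benchmark and
visualization parameter sets.  Keys are addressed as ``section.field``
(e.g. ``sim.coverage``, ``detect.cluster_window``); unknown keys raise with
the list of valid keys, and assigning a value of the wrong type raises.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .classify import FilterConfig
from .detect import DetectParams
from .simulate import SimConfig

log = logging.getLogger(__name__)


@dataclass
class BenchmarkOptions:
    n_iterations: int = 100
    base_seed: int = 0
    tolerance: int = 5


@dataclass
class VisualizeOptions:
    format: str = "svg"


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    detect: DetectParams = field(default_factory=DetectParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    benchmark: BenchmarkOptions = field(default_factory=BenchmarkOptions)
    visualize: VisualizeOptions = field(default_factory=VisualizeOptions)
    provenance: dict = field(default_factory=dict)  # config path + overrides applied

    @property
    def seed(self) -> int:
        return self.sim.seed

    def valid_keys(self) -> list[str]:
        keys = []
        for section_field in dataclasses.fields(self):
            if section_field.name == "provenance":
                continue
            section = getattr(self, section_field.name)
            for f in dataclasses.fields(section):
                keys.append(f"{section_field.name}.{f.name}")
        return keys


def _set_key(cfg: RunConfig, key: str, value: Any) -> None:
    if "." not in key:
        raise KeyError(f"unknown key {key!r}; valid keys: {', '.join(cfg.valid_keys())}")
    section_name, field_name = key.split(".", 1)
    if key not in cfg.valid_keys():
        raise KeyError(f"unknown key {key!r}; valid keys: {', '.join(cfg.valid_keys())}")
    section = getattr(cfg, section_name)
    current = getattr(section, field_name)
    if current is not None and value is not None:
        if isinstance(current, bool) != isinstance(value, bool):
            raise TypeError(f"{key}: expected {type(current).__name__}, got {type(value).__name__}")
        if isinstance(current, (int, float)) and not isinstance(value, (int, float)):
            raise TypeError(f"{key}: expected {type(current).__name__}, got {type(value).__name__}")
        if isinstance(current, (str, dict, tuple, list)) and not isinstance(value, type(current)):
            if isinstance(current, tuple) and isinstance(value, list):
                value = tuple(value)
            else:
                raise TypeError(
                    f"{key}: expected {type(current).__name__}, got {type(value).__name__}"
                )
    setattr(section, field_name, value)


def load_config(
    path: str | Path | None = None,
    overrides: Optional[dict[str, Any]] = None,
) -> RunConfig:
    """Build a RunConfig from defaults, an optional YAML file, and overrides.

    The YAML file maps sections to field dicts (``sim: {coverage: 30}``);
    ``overrides`` uses flat dotted keys and wins over the file.
    """
    cfg = RunConfig()
    applied: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise TypeError(f"{path}: config file must be a mapping")
        for section, fields in data.items():
            if not isinstance(fields, dict):
                raise TypeError(f"{path}: section {section!r} must be a mapping")
            for name, value in fields.items():
                _set_key(cfg, f"{section}.{name}", value)
                applied[f"{section}.{name}"] = value
    for key, value in (overrides or {}).items():
        _set_key(cfg, key, value)
        applied[key] = value
    # re-run validation on mutated dataclasses
    for section_name in ("sim", "detect", "filters"):
        section = getattr(cfg, section_name)
        section.__post_init__()
    cfg.provenance = {"config_file": str(path) if path else None, "overrides": applied}
    log.info("resolved config: %s", cfg.provenance)
    return cfg
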