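"""YAML/JSON pipeline configuration with strict (unknown-key rejecting) parsing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .preprocess import PreprocessConfig
from .scoring import ScoringConfig
from .simulate import SimulationConfig

__all__ = ["PipelineConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class IdentifyConfig:
    tie_tol: float = 0.0


@dataclass(frozen=True)
class StatsConfig:
    bin_width: float = 3.0
    alpha: float = 0.05
    n_components: int = 2


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    identify: IdentifyConfig = field(default_factory=IdentifyConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)


# accepted config keys per section, mapped to dataclass field names
_KEY_ALIASES: dict[str, dict[str, str]] = {
    "preprocess": {
        "tophat_window_da": "tophat_window",
        "smooth_window_pts": "smooth_window",
        "smooth_polyorder": "smooth_polyorder",
        "snr_threshold": "snr_threshold",
        "max_peaks": "max_peaks",
        "mass_min_da": None,  # folded into mass_range below
        "mass_max_da": None,
    },
    "scoring": {
        "tol_const_da": "tol_const",
        "tol_ppm": "tol_ppm",
        "symmetry_strategy": "symmetry_strategy",
    },
}


def _build_section(cls, section: str, raw: dict[str, Any]):
    aliases = _KEY_ALIASES.get(section, {})
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    extra: dict[str, Any] = {}
    for key, value in raw.items():
        if key in aliases:
            if aliases[key] is not None:
                kwargs[aliases[key]] = value
            else:
                extra[key] = value
        elif key in fields:
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key {section}.{key}")
    if section == "preprocess" and ("mass_min_da" in extra or "mass_max_da" in extra):
        lo = extra.get("mass_min_da", PreprocessConfig().mass_range[0])
        hi = extra.get("mass_max_da", PreprocessConfig().mass_range[1])
        kwargs["mass_range"] = (float(lo), float(hi))
    if section == "simulation" and "overlap_matrix" in kwargs:
        kwargs["overlap_matrix"] = np.asarray(kwargs["overlap_matrix"], dtype=float)
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Load a pipeline config from YAML (or JSON), rejecting unknown keys."""
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        for sect, kv in overrides.items():
            raw.setdefault(sect, {}).update(kv)
    known = {"preprocess": PreprocessConfig, "scoring": ScoringConfig,
             "identify": IdentifyConfig, "stats": StatsConfig,
             "simulation": SimulationConfig}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return PipelineConfig(**{
        sect: _build_section(cls, sect, raw.get(sect, {}) or {})
        for sect, cls in known.items()
    })


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of a config, for provenance logging."""

    def enc(o):
        if dataclasses.is_dataclass(o):
            return {f.name: enc(getattr(o, f.name)) for f in dataclasses.fields(o)}
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (tuple, list)):
            return [enc(x) for x in o]
        return o

    blob = json.dumps(enc(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
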