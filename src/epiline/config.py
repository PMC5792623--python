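"""Run configuration: one plain-text (YAML) file drives the whole pipeline.

Every stochastic stage derives its seed deterministically from the global
seed and the stage name, so a run is fully reproducible from the config
file alone.  Unknown fields are rejected by name; CLI flags override the
file.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from ._util import derive_seed

__all__ = ["ConfigError", "RunConfig", "DEFAULT_CONFIG", "STAGES"]


class ConfigError(ValueError):
    """Configuration schema violation; message names the offending field."""


STAGES = (
    "simulate",
    "detect-te",
    "methylation",
    "segregate",
    "map-locus",
    "cosegregate",
    "date-insertion",
    "climate",
)

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 1,
    "outdir": "epiline_run",
    "log_level": "INFO",
    "stages": list(STAGES),
    "genome": {"chrom": "chr5", "length": 80_000, "gc_fraction": 0.36},
    "te": {"length": 3_000, "truncation": 600, "inverted": True},
    "insertion": {"point": 44_500, "tsd_length": 7},
    "reads": {
        "read_len": 150,
        "insert_mean": 500.0,
        "insert_sd": 50.0,
        "coverage": 25.0,
        "error_rate": 0.0,
    },
    "detection": {"k": 31, "min_support": 3, "max_tsd": 30},
    "methylation": {"depth_mean": 30.0, "conversion_error": 0.0, "meth_threshold": 0.2},
    "cross": {
        "n_f2": 2_000,
        "marker_spacing_cm": 2.0,
        "n_markers": 21,
        "epi_locus_cm": 17.8,
        "epsilon": 0.0,
        "n_coseg": 24,
    },
    "dating": {
        "n_tips": 30,
        "length": 3_000,
        "age_years": 5.0e5,
        "rate": 6.8e-9,
        "t_div_range": [3.5e6, 5.8e6],
    },
    "climate": {
        "n_accessions": 137,
        "group_proportions": [21 / 137, 39 / 137, 77 / 137],
        "bio9_effect": 8.0,
        "alpha": 0.05,
    },
}


def _validate(user: Any, default: Any, path: str) -> Any:
    if isinstance(default, dict):
        if not isinstance(user, dict):
            raise ConfigError(f"field '{path}' must be a mapping")
        merged = copy.deepcopy(default)
        for key, value in user.items():
            if key not in default:
                raise ConfigError(f"unknown field '{path}.{key}'" if path else f"unknown field '{key}'")
            child = f"{path}.{key}" if path else key
            merged[key] = _validate(value, default[key], child)
        return merged
    if isinstance(default, bool):
        if not isinstance(user, bool):
            raise ConfigError(f"field '{path}' must be a boolean")
        return user
    if isinstance(default, (int, float)) and not isinstance(default, bool):
        if not isinstance(user, (int, float)) or isinstance(user, bool):
            raise ConfigError(f"field '{path}' must be a number")
        return user
    if isinstance(default, str):
        if not isinstance(user, str):
            raise ConfigError(f"field '{path}' must be a string")
        return user
    if isinstance(default, list):
        if not isinstance(user, list):
            raise ConfigError(f"field '{path}' must be a list")
        return user
    return user


@dataclass
class RunConfig:
    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULT_CONFIG))

    def __post_init__(self) -> None:
        unknown = [s for s in self.data.get("stages", []) if s not in STAGES]
        if unknown:
            raise ConfigError(f"unknown field 'stages': unrecognised stage {unknown[0]!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("top-level config must be a mapping")
        return cls(_validate(raw, DEFAULT_CONFIG, ""))

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        return cls(_validate(raw, DEFAULT_CONFIG, ""))

    def override(self, **kwargs: Any) -> "RunConfig":
        data = copy.deepcopy(self.data)
        for key, value in kwargs.items():
            if value is None:
                continue
            if key not in data:
                raise ConfigError(f"unknown field '{key}'")
            data[key] = value
        return RunConfig(data)

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    @property
    def outdir(self) -> Path:
        return Path(self.data["outdir"])

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)

    def config_hash(self) -> str:
        # hash only the scientific parameters: where a run is written and how
        # it logs must not change its provenance identity
        data = {k: v for k, v in self.data.items() if k not in ("outdir", "log_level")}
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
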