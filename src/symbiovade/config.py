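"""Run configuration: loading, validation, and lossless round-tripping.

Configs are flat, human-editable mappings (YAML, JSON, or TOML by file
extension).  Parameter keys are exactly the :class:`ModelParams` field names;
unknown keys anywhere are rejected with an error naming the offender, so no
NaN or negative value can reach the numeric core.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .core_model import ModelParams

__all__ = ["RunConfig", "load_config", "save_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


_TOP_KEYS = {"params", "init", "propagule", "solver", "sweep", "seed", "outdir"}
_SOLVER_KEYS = {"rtol", "atol", "method", "t_cap", "horizon", "window"}
_PROPAGULE_KEYS = {"host", "symbiont", "fraction", "host_biomass", "symbiont_biomass"}
_SWEEP_KEYS = {"kind", "edge", "axis1", "axis2", "grid",
               "axis1_range", "axis2_range", "alpha_range", "beta_range"}


@dataclass
class RunConfig:
    """Validated configuration for one run."""

    params: ModelParams
    init: Optional[list[float]] = None
    propagule: dict = field(default_factory=dict)
    solver: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    seed: int = 0
    outdir: Optional[str] = None

    def to_dict(self) -> dict:
        out: dict = {"params": self.params.to_dict(), "seed": self.seed}
        if self.init is not None:
            out["init"] = [float(v) for v in self.init]
        for key in ("propagule", "solver", "sweep"):
            val = getattr(self, key)
            if val:
                out[key] = dict(val)
        if self.outdir is not None:
            out["outdir"] = self.outdir
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "params" not in raw:
            raise ConfigError("config must contain a 'params' mapping")
        try:
            params = ModelParams.from_dict(raw["params"])
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"invalid params: {exc}") from exc
        for section, allowed in (("solver", _SOLVER_KEYS),
                                 ("propagule", _PROPAGULE_KEYS),
                                 ("sweep", _SWEEP_KEYS)):
            extra = set(raw.get(section, {})) - allowed
            if extra:
                raise ConfigError(f"unknown keys in '{section}': {sorted(extra)}")
        init = raw.get("init")
        if init is not None:
            init = [float(v) for v in init]
            if len(init) not in (2, 4):
                raise ConfigError("init must have 2 (reduced) or 4 (full) components")
            if any(v < 0 for v in init):
                raise ConfigError(f"init components must be nonnegative, got {init}")
        return cls(
            params=params,
            init=init,
            propagule=dict(raw.get("propagule", {})),
            solver=dict(raw.get("solver", {})),
            sweep=dict(raw.get("sweep", {})),
            seed=int(raw.get("seed", 0)),
            outdir=raw.get("outdir"),
        )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a run configuration (YAML/JSON/TOML by extension)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(path.read_text())
    elif suffix == ".json":
        raw = json.loads(path.read_text())
    elif suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        raise ConfigError(f"unsupported config format {suffix!r} (use .yaml/.json/.toml)")
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path: str | Path) -> Path:
    """Serialize a config so that load(save(config)) is the identity."""
    path = Path(path)
    suffix = path.suffix.lower()
    data = config.to_dict()
    if suffix in (".yaml", ".yml"):
        import yaml

        path.write_text(yaml.safe_dump(data, sort_keys=True))
    elif suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True))
    else:
        raise ConfigError(f"unsupported output config format {suffix!r}")
    return path
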