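"""Run configuration: YAML-serializable, unknown keys rejected."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from typing import Dict, List, Optional

import yaml

from .dynamics import SimConfig

__all__ = ["RunConfig", "load_config", "dump_config", "ConfigError"]


class ConfigError(ValueError):
    """Malformed run configuration."""


@dataclass
class RunConfig:
    """Everything one simulation run needs.

    Either ``fixture`` (a name from :mod:`dfbanet.fixtures`) or ``models``
    (paths + dialects) defines the community.  Bound-function overrides are
    keyed ``"<model_id>:<metabolite>"`` with a BoundFunction dict value.
    """

    fixture: Optional[str] = None
    models: List[Dict[str, str]] = field(default_factory=list)  # {path, dialect}
    metabolites: Dict[str, float] = field(default_factory=dict)  # id -> y0
    inflow: Dict[str, float] = field(default_factory=dict)       # id -> rate
    biomass: Dict[str, float] = field(default_factory=dict)      # model id -> x0
    bound_overrides: Dict[str, dict] = field(default_factory=dict)
    t_final: float = 5.0
    output_dir: str = "dfbanet_out"
    include_self_loops: bool = True
    mediated_in_heuristic: bool = True
    refine: bool = True
    significance_threshold: float = 0.01
    seed: int = 0  # only for property-test random models
    tolerances: Dict[str, float] = field(default_factory=dict)

    def sim_config(self) -> SimConfig:
        cfg = SimConfig(refine=self.refine)
        valid = {f.name for f in fields(SimConfig)}
        for k, v in self.tolerances.items():
            if k not in valid:
                raise ConfigError(f"unknown tolerance {k!r}")
            setattr(cfg, k, v)
        return cfg

    def validate(self) -> None:
        if self.fixture is None and not self.models:
            raise ConfigError("config needs either 'fixture' or 'models'")
        if self.t_final <= 0:
            raise ConfigError("t_final must be positive")
        self.sim_config()


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"YAML parse error in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg


def dump_config(cfg: RunConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)
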