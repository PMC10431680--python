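"""Run configuration: serialisable bundle of model, engine and numeric settings.

A config file is a flat YAML/JSON mapping.  Parameter keys use the
conventional names (v0, F, K, lambda_W, ..., p_init, p_stress, eta,
eta_amp, eta_freq, or the substituted pair p_prod/p_frac); remaining keys
configure the run itself.  Unknown keys are rejected by name, and a
round-tripped config reproduces the run byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .network import MODIFIED_PARAMETER_NAMES, ParameterSet, StressProtocol
from .simulation import SimulationSettings

__all__ = ["RunConfig", "load_config", "save_config"]

_RUN_KEYS = {
    "model", "engine", "n", "seed", "activity_source", "out_dir",
    "t_burnin_start", "t_stress", "t_end",
    "dt", "sample_dt", "newton_tol", "newton_max_iter", "negative_floor",
    "ode_method",
}
_PARAM_KEYS = set(MODIFIED_PARAMETER_NAMES) | {"p_prod", "p_frac", "production_form"}


@dataclass
class RunConfig:
    model: str = "core"                 # core | modified
    engine: str = "cle"                 # ode | cle | ssa
    params: ParameterSet = field(default_factory=ParameterSet)
    protocol: StressProtocol = field(default_factory=StressProtocol)
    settings: SimulationSettings = field(default_factory=SimulationSettings)
    n: int = 1
    seed: int = 0
    activity_source: str = "free"
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.model not in ("core", "modified"):
            raise ValueError(f"model must be 'core' or 'modified', got {self.model!r}")
        if self.engine not in ("ode", "cle", "ssa"):
            raise ValueError(f"engine must be ode/cle/ssa, got {self.engine!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def to_dict(self) -> dict:
        out = dict(
            model=self.model, engine=self.engine, n=self.n, seed=self.seed,
            activity_source=self.activity_source, out_dir=self.out_dir,
            t_burnin_start=self.protocol.t_burnin_start,
            t_stress=self.protocol.t_stress, t_end=self.protocol.t_end,
            dt=self.settings.dt, sample_dt=self.settings.sample_dt,
            newton_tol=self.settings.newton_tol,
            newton_max_iter=self.settings.newton_max_iter,
            negative_floor=self.settings.negative_floor,
            ode_method=self.settings.ode_method,
        )
        out.update(self.params.to_dict())
        return out

    def config_hash(self) -> str:
        """Stable short hash identifying the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        unknown = set(data) - _RUN_KEYS - _PARAM_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        param_data = {k: v for k, v in data.items() if k in _PARAM_KEYS}
        params = ParameterSet.from_dict(param_data)
        protocol = StressProtocol(
            t_burnin_start=data.get("t_burnin_start", -10.0),
            t_stress=data.get("t_stress", 0.0),
            t_end=data.get("t_end", 200.0),
        )
        settings = SimulationSettings(
            dt=data.get("dt", 0.005),
            sample_dt=data.get("sample_dt", 0.01),
            newton_tol=data.get("newton_tol", 1e-10),
            newton_max_iter=data.get("newton_max_iter", 20),
            negative_floor=data.get("negative_floor", 0.02),
            ode_method=data.get("ode_method", "implicit"),
        )
        return cls(
            model=data.get("model", "core"),
            engine=data.get("engine", "cle"),
            params=params, protocol=protocol, settings=settings,
            n=data.get("n", 1), seed=data.get("seed", 0),
            activity_source=data.get("activity_source", "free"),
            out_dir=data.get("out_dir", "."),
        )


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config file; ``None`` or an empty file gives defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
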