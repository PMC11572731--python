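"""Run configuration: YAML/JSON parsing and digests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError
from .generate import GeneratorConfig
from .models import ModelSpec, ROLES


@dataclasses.dataclass
class MediationConfig:
    n_boot: int = 25000
    ci_level: float = 0.95
    stratified: bool = False
    total_tol: float = 1e-6

    def validate(self):
        if self.n_boot < 100:
            raise ConfigurationError("mediation.n_boot: must be >= 100")
        if not 0 < self.ci_level < 1:
            raise ConfigurationError("mediation.ci_level: must be in (0, 1)")


@dataclasses.dataclass
class SensitivityConfig:
    rho_min: float = -0.9
    rho_max: float = 0.9
    step: float = 0.01

    def validate(self):
        if not (-1 < self.rho_min < self.rho_max < 1):
            raise ConfigurationError(
                "sensitivity: need -1 < rho_min < rho_max < 1")
        if self.step <= 0:
            raise ConfigurationError("sensitivity.step: must be > 0")

    def grid(self):
        import numpy as np
        return np.round(np.arange(self.rho_min, self.rho_max + 1e-12, self.step), 10)


@dataclasses.dataclass
class RunConfig:
    """Everything one analysis run needs, loadable from YAML or JSON."""

    generator: GeneratorConfig = dataclasses.field(default_factory=GeneratorConfig)
    mediation: MediationConfig = dataclasses.field(default_factory=MediationConfig)
    sensitivity: SensitivityConfig = dataclasses.field(default_factory=SensitivityConfig)
    model_overrides: dict = dataclasses.field(default_factory=dict)
    seed: int | None = None
    log_level: str = "INFO"

    def validate(self):
        self.generator.validate()
        self.mediation.validate()
        self.sensitivity.validate()

    def specs(self) -> dict:
        """Materialize ModelSpec overrides keyed by role."""
        out = {}
        for role, payload in self.model_overrides.items():
            if role not in ROLES:
                raise ConfigurationError(f"model_overrides: unknown role {role!r}")
            out[role] = ModelSpec(role=role, **payload)
        return out

    def digest(self) -> str:
        """Hash of all semantic fields; timestamps and log level excluded."""
        payload = {
            "generator": dataclasses.asdict(self.generator),
            "mediation": dataclasses.asdict(self.mediation),
            "sensitivity": dataclasses.asdict(self.sensitivity),
            "model_overrides": self.model_overrides,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, payload: Mapping) -> "RunConfig":
        payload = dict(payload)
        known = {"generator", "mediation", "sensitivity", "model_overrides",
                 "seed", "log_level"}
        unknown = set(payload) - known
        if unknown:
            raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
        kw = {}
        if "generator" in payload:
            kw["generator"] = GeneratorConfig.from_dict(payload["generator"])
        if "mediation" in payload:
            kw["mediation"] = MediationConfig(**payload["mediation"])
        if "sensitivity" in payload:
            kw["sensitivity"] = SensitivityConfig(**payload["sensitivity"])
        kw["model_overrides"] = payload.get("model_overrides", {})
        kw["seed"] = payload.get("seed")
        kw["log_level"] = payload.get("log_level", "INFO")
        config = cls(**kw)
        config.validate()
        return config

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        try:
            text = path.read_text()
        except OSError as exc:
            raise ConfigurationError(f"config: cannot read {path}: {exc}") from exc
        try:
            payload = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"config: invalid YAML/JSON in {path}: {exc}") from exc
        if not isinstance(payload, Mapping):
            raise ConfigurationError(f"config: top level of {path} must be a mapping")
        return cls.from_dict(payload)


def default_config() -> RunConfig:
    """The packaged configuration reproducing the study-calibrated cohort."""
    with resources.files("prl_mediation.data").joinpath("default_config.yaml").open() as fh:
        payload = yaml.safe_load(fh)
    return RunConfig.from_dict(payload)
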