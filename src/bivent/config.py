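"""Scenario configuration: schema-validated YAML/JSON describing a virtual
animal, the protocol settings and the cohort layout.

Validation is strict (unknown keys are rejected, every invariant of the
parameter containers is enforced) and the fully-materialised configuration
— every default made explicit — round-trips losslessly.  The JSON schema
is published via :func:`config_schema`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError
from .params import AnimalModel
from .protocol import ProtocolConfig


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n: int = Field(default=18, ge=1)
    escalation_n: int = Field(default=8, ge=0)
    seed: int = Field(default=1, ge=0)


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    animal: AnimalModel = Field(default_factory=AnimalModel)
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)

    def materialised(self) -> dict:
        return self.model_dump()

    def hash(self) -> str:
        blob = json.dumps(self.materialised(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def config_schema() -> dict:
    """JSON schema of the scenario configuration."""
    return ScenarioConfig.model_json_schema()


def _format_validation_error(e: ValidationError) -> str:
    lines = []
    for err in e.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def validate_config(path) -> ScenarioConfig:
    """Load and validate a scenario config file (YAML or JSON).

    Raises ConfigError naming every violating key.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"unparseable config {path}: {e}") from e
    if raw is None:
        raw = {}
    try:
        return ScenarioConfig.model_validate(raw)
    except ValidationError as e:
        raise ConfigError(f"invalid config {path}: {_format_validation_error(e)}") from e


def nominal_config_path() -> Path:
    return Path(__file__).parent / "data" / "nominal.yaml"


def load_nominal() -> ScenarioConfig:
    """The packaged nominal scenario (all defaults, stated explicitly)."""
    return validate_config(nominal_config_path())


def write_config(cfg: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.materialised(), sort_keys=False))
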