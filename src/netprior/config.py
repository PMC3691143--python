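"""Schema-validated run configuration (YAML/JSON document; CLI flags override)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class LFMSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    burn_in: int = Field(100_000, gt=0)
    samples: int = Field(500_000, gt=0)
    param_move_period: int = Field(10, gt=0)
    cov_update_period: int = Field(100, gt=0)
    edge_prior_rho: float = Field(0.05, gt=0, lt=1)
    param_bounds: tuple[float, float] = (0.1, 1000.0)
    likelihood_form: str = "asymmetric"
    fix_params: bool = False


class SimulationSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    m: int = Field(20, ge=2)
    n_sources: int = Field(5, ge=1)
    alpha: float = Field(10.0, gt=0)
    beta: float = Field(10.0, gt=0)
    n_samples: int = Field(100, ge=1)
    n_categories: int = Field(3, ge=2)
    replicates: int = Field(10, ge=1)
    seed_graph_size: int = Field(200, ge=5)


class BNSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_parents: int = Field(5, ge=0)
    search: str = "exact"  # exact | hill_climb
    restarts: int = Field(3, ge=1)


class RunConfig(BaseModel):
    """Top-level configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    method: str = "NOM"
    seed: int = 0
    lfm: LFMSettings = LFMSettings()
    simulation: SimulationSettings = SimulationSettings()
    bn: BNSettings = BNSettings()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(doc)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
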