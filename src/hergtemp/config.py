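"""Run configuration schema for the command-line pipeline."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field


class InferenceOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_starts: int = Field(10, ge=1)
    n_iter: int = Field(20000, ge=100)
    n_chains: int = Field(3, ge=1)
    thin: int = Field(10, ge=1)
    hierarchical_iters: int = Field(5000, ge=100)


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    temperatures_C: list[float] = [25.0, 27.0, 30.0, 33.0, 37.0]
    Ko_mM: float = Field(4.0, gt=0)
    Ki_mM: float = Field(110.0, gt=0)
    protocol: str = "staircase-fixture"
    n_wells: int = Field(30, ge=1)
    seed: int = 1
    dt_ms: float = Field(1.0, gt=0)
    noise_fraction: float = Field(0.05, ge=0)
    well_log_sd: float | None = Field(None, ge=0)  # None: generator default
    abs_tol: float = Field(1e-8, gt=0)
    rel_tol: float = Field(1e-10, gt=0)
    inference: InferenceOptions = InferenceOptions()

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.model_validate(json.load(f))

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def write(self, path):
        Path(path).write_text(json.dumps(self.model_dump(), indent=2))
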