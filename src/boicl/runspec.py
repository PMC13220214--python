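"""YAML run specification: pool/labels paths, providers, campaign knobs.

The run spec is the single file a shell user edits; every default is
printed back into the run manifest so no setting is ever implicit.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from .campaign import CampaignConfig

SCHEMA_VERSION = 1


class EmbedderSpec(BaseModel):
    kind: Literal["hashing"] = "hashing"
    dimension: int = Field(default=256, ge=2)
    seed: int = 0


class BackendSpec(BaseModel):
    """Mock backend settings; the truth table is the labels file."""

    kind: Literal["mock"] = "mock"
    noise_sd: float = Field(default=0.0, ge=0.0)
    relative_noise: Optional[float] = Field(default=None, ge=0.0)  # fraction of label range
    bias: float = 0.0
    miscalibration: float = Field(default=1.0, gt=0.0)
    seed: int = 0


class ArmSpec(BaseModel):
    name: str
    kind: Literal["ucb", "greedy", "ei", "random"] = "ucb"
    surrogate: Literal["icl", "gp"] = "icl"
    schedule: Optional[str] = None


class RunSpec(BaseModel):
    schema_version: int = SCHEMA_VERSION
    pool: str
    labels: str
    campaign: CampaignConfig = Field(default_factory=CampaignConfig)
    embedder: EmbedderSpec = Field(default_factory=EmbedderSpec)
    backend: BackendSpec = Field(default_factory=BackendSpec)
    # benchmark mode only
    arms: list[ArmSpec] = Field(default_factory=list)
    replicates: int = Field(default=5, ge=1)


def load_run_spec(path: str | Path) -> RunSpec:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunSpec.model_validate(raw)
    except ValidationError as err:
        lines = [
            f"  {'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ValueError("invalid run spec:\n" + "\n".join(lines)) from err
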