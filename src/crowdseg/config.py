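"""Campaign configuration.

The five controlled parameters — training-score cutoff (``ts_min``),
running-score cutoff (``rs_min``), minimum annotations per task (``n_min``),
per-pixel majority-vote threshold (``mv``) and difficulty review threshold
(``rt``) — plus the auxiliary knobs the protocol leaves open (running-score
cadence and window, QA sampling rate, expert throughput constants, seed).

The shipped default is a bowel / abdominal-wall campaign: n = 5 with a
vote threshold of 4 for bowel and 2 for abdominal wall, and a review
threshold of 0.4. The TS/RS cutoffs of 0.5 are repo conventions and should
be overridden to match any particular deployment.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError


class StructureParams(BaseModel):
    """Per-structure consensus parameters."""

    model_config = ConfigDict(frozen=True)

    n_min: int = Field(default=5, ge=1)
    mv: int = Field(ge=1)
    #: when a task attracts more than n_min qualified annotations, rescale
    #: the vote threshold as ceil(mv / n_min * n_used) to preserve the
    #: voting fraction; set False to keep mv as an absolute count.
    scale_mv: bool = True

    @model_validator(mode="after")
    def _check_mv(self) -> "StructureParams":
        if self.mv > self.n_min:
            raise ValueError(f"mv ({self.mv}) must be <= n_min ({self.n_min})")
        return self


class CampaignConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    structures: dict[str, StructureParams]
    ts_min: float = Field(default=0.5, ge=0.0, le=1.0)
    rs_min: float = Field(default=0.5, ge=0.0, le=1.0)
    n_training_gold: int = Field(default=10, ge=1)
    #: expected ordinary tasks between running-gold insertions
    rs_cadence: int = Field(default=20, ge=1)
    #: number of most recent running-gold tests averaged into the RS
    rs_window: int = Field(default=10, ge=1)
    rt: float = Field(default=0.4, ge=0.0, le=1.0)
    qa_sampling_rate: float = Field(default=0.1, ge=0.0, le=1.0)
    expert_seconds_per_frame: float = Field(default=120.3, gt=0.0)
    experts_available: int = Field(default=4, ge=1)
    expert_hours_per_day: float = Field(default=1.0, gt=0.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_structures(self) -> "CampaignConfig":
        if not self.structures:
            raise ValueError("at least one structure must be configured")
        return self

    def structure_params(self, structure: str) -> StructureParams:
        try:
            return self.structures[structure]
        except KeyError:
            raise ConfigurationError(
                f"structure {structure!r} is not configured "
                f"(known: {sorted(self.structures)})"
            ) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CampaignConfig":
        with open(path, "r", encoding="utf-8") as fh:
            payload: Any = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise ConfigurationError(f"{path}: expected a YAML mapping")
        try:
            return cls.model_validate(payload)
        except ValueError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)


def default_config(**overrides: Any) -> CampaignConfig:
    """The shipped bowel / abdominal-wall campaign configuration."""
    base: dict[str, Any] = {
        "structures": {
            "bowel": {"n_min": 5, "mv": 4},
            "abdominal_wall": {"n_min": 5, "mv": 2},
        }
    }
    base.update(overrides)
    return CampaignConfig.model_validate(base)
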