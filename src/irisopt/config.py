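"""Run configuration: YAML-backed, validated, hashable for provenance."""

from __future__ import annotations

import hashlib
import json

import yaml
from pydantic import BaseModel, Field, field_validator

from .engine import IRIS_DIAMETERS_MM

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """Pipeline configuration; defaults are the standard clinical values."""

    gtv_to_ctv_mm: float = Field(2.0, ge=0)
    ctv_to_ptv_mm: float = Field(4.0, ge=0)
    collimator_diameters: tuple[float, ...] = IRIS_DIAMETERS_MM
    coverage_required_pct: float = Field(90.0, gt=0, le=100)
    w: float = Field(0.0, ge=0)
    v_lung_cm3: float = Field(1500.0, gt=0)
    spacing_mm: float = Field(1.0, gt=0)
    histogram_levels: int = Field(1001, ge=2)
    seed: int = Field(0, ge=0)
    literal_minimize: bool = False

    @field_validator("collimator_diameters")
    @classmethod
    def _increasing(cls, v: tuple[float, ...]) -> tuple[float, ...]:
        if len(v) == 0 or any(b <= a for a, b in zip(v, v[1:])) or v[0] <= 0:
            raise ValueError("collimator diameters must be positive and strictly increasing")
        return v

    def config_hash(self) -> str:
        """Stable short hash of the configuration, embedded in every artifact."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | None) -> RunConfig:
    """Load a YAML run config; None gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
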