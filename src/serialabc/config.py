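"""Validated run configuration (YAML) and provenance."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .coalescent import MutationModel
from .scenarios import GenerationClock, RainfallSeries, SamplingDesign, mongola_design, punta_europa_rainfall

__all__ = ["RunConfig", "load_config", "provenance"]


class DesignConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    sample_dates: list[dt.date]
    sample_sizes: list[int]
    n_loci: int = 13
    spray_dates: list[dt.date] = Field(default_factory=list)

    def build(self) -> SamplingDesign:
        return SamplingDesign(
            sample_dates=list(self.sample_dates),
            sample_sizes=list(self.sample_sizes),
            n_loci=self.n_loci,
            spray_dates=list(self.spray_dates),
        )


class MutationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    median_rate: float = 6.34e-4
    p_geom: float = 0.36
    n_states: int = 40
    rate_shape: float = 0.7

    def build(self) -> MutationModel:
        return MutationModel(**self.model_dump())


class RainfallConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    months: list[str]  # "YYYY-MM"
    values_mm: list[float]

    def build(self) -> RainfallSeries:
        months = [(int(m[:4]), int(m[5:7])) for m in self.months]
        return RainfallSeries(months=months, values_mm=list(self.values_mm))


class RunConfig(BaseModel):
    """Structured configuration for the CLI; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    scenarios: list[int] = Field(default_factory=lambda: [1, 2, 3, 4, 5, 6])
    n_per_scenario: int = 10000
    retention_fraction: float = 0.01
    generations_per_year: float = 18.0
    clock_candidates: list[float] = Field(default_factory=lambda: [12.0, 18.0, 24.0])
    design: DesignConfig | None = None
    mutation: MutationConfig = Field(default_factory=MutationConfig)
    rainfall: RainfallConfig | None = None
    regression_adjust: bool = False
    output_dir: Path = Path("serialabc_out")

    @field_validator("retention_fraction")
    @classmethod
    def _frac(cls, v: float) -> float:
        if not 0 < v <= 1:
            raise ValueError("retention_fraction must be in (0, 1]")
        return v

    @field_validator("scenarios")
    @classmethod
    def _scen(cls, v: list[int]) -> list[int]:
        if not v or any(s not in range(1, 7) for s in v):
            raise ValueError("scenarios must be a non-empty subset of 1..6")
        return v

    def build_design(self) -> SamplingDesign:
        return self.design.build() if self.design else mongola_design()

    def build_clock(self, gpy: float | None = None) -> GenerationClock:
        design = self.build_design()
        return GenerationClock(gpy or self.generations_per_year, design.sample_dates[-1])

    def build_rainfall(self) -> RainfallSeries:
        return self.rainfall.build() if self.rainfall else punta_europa_rainfall()


def load_config(path: str | Path | None) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def provenance(config: RunConfig, extra: dict | None = None) -> dict:
    """Machine-readable provenance block written next to every CLI output."""
    dump = config.model_dump(mode="json")
    digest = hashlib.sha256(json.dumps(dump, sort_keys=True).encode()).hexdigest()
    return {
        "package": "serialabc",
        "version": __version__,
        "config_sha256": digest,
        "config": dump,
        "numpy": np.__version__,
        "python": platform.python_version(),
        **(extra or {}),
    }
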