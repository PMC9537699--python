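"""Pipeline configuration.

A single validated configuration object drives the end-to-end pipeline
(simulate → quantify → compare).  Defaults encode the study conventions:
a 1.1 μm perinuclear band, Otsu auto-thresholding, 200 μm counting regions,
α = q = 0.05, and an onset cohort design in which control and mutant
relative nuclear positions coincide at P8/P10 and separate by Δp = 0.25
from P12 on.  Unknown keys are rejected and configs round-trip losslessly
through YAML.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator


class CohortDesign(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_per_group: int = Field(10, ge=1)
    ages: tuple[str, ...] = ("P8", "P10", "P12", "P14")
    onset_age: str | None = "P12"
    baseline: float = Field(0.75, ge=0.0, le=1.0)
    delta: float = Field(0.25, ge=0.0, le=1.0)
    control_sd: float = Field(0.05, ge=0.0)
    mutant_sd: float = Field(0.08, ge=0.0)

    @model_validator(mode="after")
    def _onset_in_ages(self):
        if self.onset_age is not None and self.onset_age not in self.ages:
            raise ValueError(f"onset_age {self.onset_age!r} not in ages {self.ages}")
        return self


class RecruitmentDesign(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_per_group: int = Field(3, ge=1)
    # reporter envelope-enrichment factor k per group; k = 1 is unenriched
    enrichment: dict[str, float] = {"nesp4": 3.0, "empty": 1.0}
    cell_length: float = Field(30.0, gt=0)
    axis_curvature: float = 0.3


class CisternaeDesign(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_cells_per_group: int = Field(5, ge=1)
    segments_per_cell: int = Field(7, ge=2)
    segment_length: float = Field(2.0, gt=0)
    mean_gap: dict[str, float] = {"control": 0.5, "mutant": 2.0}
    sd_gap: float = Field(0.1, ge=0.0)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    band_width: float = Field(1.1, gt=0, description="perinuclear band width, μm")
    threshold_method: Literal["otsu", "isodata"] = "otsu"
    region_span: float = Field(200.0, gt=0, description="counting region, μm")
    alpha: float = Field(0.05, gt=0, lt=1)
    q: float = Field(0.05, gt=0, lt=1)
    channel_map: dict[str, int] = {"dapi": 0, "cell": 1, "reporter": 2}
    write_images: bool = False
    cohort: CohortDesign = CohortDesign()
    recruitment: RecruitmentDesign = RecruitmentDesign()
    cisternae: CisternaeDesign = CisternaeDesign()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=True)
        )

    def content_hash(self) -> str:
        canonical = json.dumps(
            json.loads(self.model_dump_json()), sort_keys=True
        ).encode()
        return hashlib.sha256(canonical).hexdigest()
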