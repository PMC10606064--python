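"""Validated run configuration for the end-to-end study pipeline.

Defaults reproduce the study conditions: binding truths for quercetin
and the two loosely bound analogues, aggregation half-inhibition values
for the three quantified compounds, the lead-compound viability curve,
a two-population migration experiment with a 0.68 speed ratio, and a
39%-coverage single-cell image.  Unknown keys are rejected.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import ValidationError

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class BindingTruth(_Strict):
    compound: str
    f_a: float = Field(gt=0, le=1)
    K_D_M: float = Field(gt=0)


class AssemblyTruth(_Strict):
    compound: str
    half_inhibition_uM: float = Field(gt=0)


class ViabilityTruth(_Strict):
    compound: str
    cell_line: str
    m: float = Field(gt=0)
    Dm_uM: float = Field(gt=0)


class MigrationSettings(_Strict):
    reference_group: str = "shCTRL"
    treated_group: str = "shTau"
    reference_speed_um_min: float = Field(0.5, gt=0)
    speed_ratio: float = Field(0.68, gt=0)
    persistence_time_min: float = Field(60.0, gt=0)
    n_cells: int = Field(80, ge=5)
    n_frames: int = Field(61, ge=2)
    total_time_min: float = Field(600.0, gt=0)
    step_cv: float = Field(0.3, ge=0)


class ImagingSettings(_Strict):
    width: int = Field(512, ge=64)
    height: int = Field(512, ge=64)
    coverage: float = Field(0.39, gt=0, lt=1)
    cell_mask_fraction: float = Field(0.25, gt=0, lt=1)
    noise_sd_rel_contrast: float = Field(0.10, ge=0)


class RunConfig(_Strict):
    """Everything `run_pipeline` needs; YAML-loadable, unknown keys rejected."""

    seed: int = 0
    output_dir: Path = Path("tauquant_out")
    synthetic: bool = True
    noise_cv: float = Field(0.0, ge=0)
    inner_filter: bool = True
    ic50_rule: Literal["interpolated", "literal"] = "interpolated"
    r2_flag: float = Field(0.95, gt=0, le=1)
    fit_tolerance: float = Field(1e-10, gt=0)

    # input files, used when synthetic is false
    titrations_csv: Optional[Path] = None
    timecourses_csv: Optional[Path] = None
    plates_csv: Optional[Path] = None
    tracks_csv: Optional[Path] = None
    tracks_group_col: str = "group"

    binding_truths: list[BindingTruth] = [
        BindingTruth(compound="QCT", f_a=0.12, K_D_M=2.4e-6),
        BindingTruth(compound="1", f_a=0.39, K_D_M=7.0e-6),
        BindingTruth(compound="5", f_a=0.38, K_D_M=6.4e-6),
    ]
    assembly_truths: list[AssemblyTruth] = [
        AssemblyTruth(compound="QCT", half_inhibition_uM=17.3),
        AssemblyTruth(compound="1", half_inhibition_uM=92.0),
        AssemblyTruth(compound="4", half_inhibition_uM=9.7),
    ]
    viability_truths: list[ViabilityTruth] = [
        ViabilityTruth(compound="9", cell_line="U87 shCTRL", m=1.0, Dm_uM=1.6),
    ]
    migration: MigrationSettings = MigrationSettings()
    imaging: ImagingSettings = ImagingSettings()

    @field_validator("binding_truths", "assembly_truths", "viability_truths")
    @classmethod
    def _non_empty(cls, v):
        if not v:
            raise ValueError("truth list must not be empty")
        return v


def load_config(path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"{path}: config file not found")
    data = yaml.safe_load(path.read_text()) or {}
    try:
        return RunConfig(**data)
    except Exception as exc:  # pydantic error -> package validation error
        raise ValidationError(f"{path}: invalid configuration: {exc}") from None
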