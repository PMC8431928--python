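"""Typed schema of the profiling report JSON (and the shipped schema file)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

from pydantic import BaseModel, Field


class Interval(BaseModel):
    estimate: float
    lower: float
    upper: float


class CaterpillarEntry(BaseModel):
    label: str
    rank: int
    n_patients: int
    unadjusted: Interval
    adjusted: Interval


class Caterpillar(BaseModel):
    centres: list[CaterpillarEntry]


class OutcomeProfile(BaseModel):
    """MOR/rankability/R^2 block for one outcome indicator."""

    tau_unadjusted: float
    tau_adjusted: float
    mor_unadjusted: float
    mor_adjusted: float
    pct_decrease_mor: int
    rankability: float
    nagelkerke_r2: Optional[float] = None
    caterpillar: Caterpillar
    converged: bool


class ProcessProfile(BaseModel):
    """Variation block for a process-of-care indicator."""

    tau_unadjusted: float
    tau_adjusted: float
    mor_adjusted: Optional[float] = None  # logit-scale indicators only
    rankability: float
    caterpillar: Caterpillar
    converged: bool


class ExposureEffect(BaseModel):
    exposure: str
    outcome: str
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    adjustment_set: list[str]


class StructureTest(BaseModel):
    indicator: str
    p_value: float
    mc_se: float
    collapse_45: bool
    table: list[list[int]]


class PooledCoefficient(BaseModel):
    estimate: float
    se: float
    odds_ratio: Optional[float] = None
    ci_lower: float
    ci_upper: float


class Descriptive(BaseModel):
    variable: str
    kind: str
    test: str
    p_value: float
    group_stats: dict


class ProfileReport(BaseModel):
    """Contract of the pipeline's JSON report."""

    seed: int
    n_patients: int
    n_centres: int
    excluded_centres: list[dict] = Field(default_factory=list)
    n_excluded_patients: int = 0
    survival_n: int
    survival_pct: float
    missing_cpc_pct: float
    m_imputations: int
    complete_case: bool
    outcomes: dict[str, OutcomeProfile]
    process: dict[str, ProcessProfile]
    case_mix_effects: dict[str, dict[str, PooledCoefficient]]
    als_effect_on_cpc: Optional[ExposureEffect] = None
    structure: list[StructureTest] = Field(default_factory=list)
    posthoc_training_effect: Optional[ExposureEffect] = None
    descriptives: list[Descriptive] = Field(default_factory=list)
    errors: dict[str, str] = Field(default_factory=dict)

    @classmethod
    def schema_path(cls) -> Path:
        return Path(__file__).parent / "schemas" / "profile_report.schema.json"


def write_report_schema(directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "profile_report.schema.json").write_text(
        json.dumps(ProfileReport.model_json_schema(), indent=2, sort_keys=True)
        + "\n"
    )
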