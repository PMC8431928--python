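"""Configuration objects for simulation and the profiling pipeline.

The simulation defaults emulate a 12-centre in-hospital cardiac arrest
(IHCA) cohort of 701 patients: Utstein-style case-mix marginals, a latent
proportional-odds process for the discharge Cerebral Performance Category
(CPC, 0 asymptomatic ... 5 dead) whose top category is in-hospital death,
centre random intercepts on the logit scale for outcomes and for
rapid-response-score (RRS) reporting, a centre-level shift in time to
advanced life support (ALS), and missing-at-random missingness driven by
an observed covariate.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, \
    model_validator


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


class _StrictModel(BaseModel):
    """Base model that surfaces validation failures as ConfigurationError."""

    def __init__(self, **data):
        try:
            super().__init__(**data)
        except ValidationError as exc:
            raise ConfigurationError(str(exc)) from exc


#: per-centre inclusion counts summing to 701 with median 49, mimicking the
#: skewed centre sizes typical of a voluntary multicentre registry
DEFAULT_CENTRE_SIZES = [15, 20, 28, 35, 42, 47, 51, 58, 70, 85, 110, 140]


class Marginals(_StrictModel):
    """Marginal distributions of case-mix and arrest-context covariates.

    Defaults are calibrated to a typical IHCA cohort (median age ~69,
    median Charlson 1-2, ~79% witnessed arrests, ~26% shockable rhythm).
    All are overridable.
    """

    age_mean: float = 69.0
    age_sd: float = 13.0
    age_bounds: tuple[float, float] = (18.0, 100.0)
    female_p: float = 0.354
    charlson_mean: float = 1.8
    charlson_max: int = 12
    pre_mrs_probs: list[float] = Field(
        default=[0.374, 0.338, 0.132, 0.123, 0.025, 0.008]
    )
    pre_cpc_probs: list[float] = Field(default=[0.778, 0.145, 0.052, 0.024, 0.001])
    witnessed_p: float = 0.786
    weekend_p: float = 0.28
    shift_probs: dict[str, float] = Field(
        default={"day": 0.348, "evening": 0.494, "night": 0.158}
    )
    shockable_p: float = 0.262
    location_probs: dict[str, float] = Field(
        default={
            "ward": 0.452,
            "emergency_department": 0.100,
            "icu": 0.150,
            "cardiac_care_unit": 0.117,
            "radiology": 0.057,
            "operating_theatre": 0.046,
            "other": 0.078,
        }
    )
    rrs_base_logit: float = -0.72
    als_mean: float = 2.5
    als_patient_sd: float = 2.0
    training_twice_p: float = 0.333
    intensivist_24_7_p: float = 0.417
    als_physician_24_7_p: float = 0.833

    @model_validator(mode="after")
    def _check_probs(self) -> "Marginals":
        for name in ("female_p", "witnessed_p", "weekend_p", "shockable_p",
                     "training_twice_p", "intensivist_24_7_p",
                     "als_physician_24_7_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("pre_mrs_probs", "pre_cpc_probs"):
            p = getattr(self, name)
            if any(x < 0 for x in p) or abs(sum(p) - 1.0) > 1e-6:
                raise ConfigurationError(f"{name} must be a probability vector")
        for name in ("shift_probs", "location_probs"):
            p = getattr(self, name)
            if any(x < 0 for x in p.values()) or abs(sum(p.values()) - 1.0) > 1e-6:
                raise ConfigurationError(f"{name} must be a probability vector")
        return self


class SimConfig(_StrictModel):
    """Ground-truth parameters of a synthetic multicentre cohort.

    ``tau_outcome`` and ``tau_process`` are the SDs (logit scale) of the
    centre random intercepts for the latent outcome process and for RRS
    reporting; ``sigma_als_centre`` is the SD in minutes of centre-level
    shifts in mean time to ALS. ``beta`` maps covariate names to log-odds
    coefficients of the shared outcome linear predictor; ``theta`` holds
    the five proportional-odds thresholds separating CPC categories 0-5
    (convention: logit P(Y <= k) = theta_k - eta, so positive beta means
    worse outcome).
    """

    n_centres: int = Field(default=12, gt=0)
    patients_per_centre: Union[int, list[int]] = Field(
        default_factory=lambda: list(DEFAULT_CENTRE_SIZES)
    )
    tau_outcome: float = Field(default=0.19, ge=0.0)
    tau_process: float = Field(default=1.1, ge=0.0)
    sigma_als_centre: float = Field(default=0.8, ge=0.0)
    beta: dict[str, float] = Field(
        default={"age": 0.0223, "charlson": 0.157, "pre_mrs": 0.095,
                 "pre_cpc": 0.358}
    )
    theta: list[float] = Field(default=[0.53, 0.95, 1.17, 1.29, 1.34])
    missing_rates: dict[str, float] = Field(
        default={"cpc_discharge": 0.017, "pre_cpc": 0.036, "pre_mrs": 0.039,
                 "time_to_als": 0.01, "shift": 0.033}
    )
    mar_driver: str = "age"
    mar_slope: float = 1.0
    marginals: Marginals = Field(default_factory=Marginals)
    seed: int = 0

    @field_validator("theta")
    @classmethod
    def _theta_increasing(cls, v: list[float]) -> list[float]:
        if len(v) != 5:
            raise ConfigurationError("theta must list 5 thresholds (CPC 0-5)")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ConfigurationError("theta must be strictly increasing")
        return v

    @field_validator("missing_rates")
    @classmethod
    def _rates_in_unit(cls, v: dict[str, float]) -> dict[str, float]:
        for k, r in v.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"missing rate for {k} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_sizes(self) -> "SimConfig":
        if isinstance(self.patients_per_centre, list):
            if len(self.patients_per_centre) != self.n_centres:
                raise ConfigurationError(
                    "patients_per_centre list length must equal n_centres"
                )
            if any(n <= 0 for n in self.patients_per_centre):
                raise ConfigurationError("centre sizes must be positive")
        elif self.patients_per_centre <= 0:
            raise ConfigurationError("patients_per_centre must be positive")
        return self

    def centre_sizes(self) -> list[int]:
        if isinstance(self.patients_per_centre, int):
            return [self.patients_per_centre] * self.n_centres
        return list(self.patients_per_centre)


class PipelineConfig(_StrictModel):
    """End-to-end profiling run: input source, filters, models, outputs."""

    sim: Optional[SimConfig] = None
    cohort_path: Optional[str] = None
    centres_path: Optional[str] = None
    min_patients_per_centre: int = Field(default=10, ge=0)
    case_mix: list[str] = Field(
        default=["age", "charlson", "pre_mrs", "pre_cpc"]
    )
    als_adjustment_set: list[str] = Field(
        default=["weekend", "shift", "witnessed", "rrs_reported"]
    )
    m_imputations: int = Field(default=5, ge=1)
    mice_iterations: int = Field(default=10, ge=1)
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    quadrature_nodes: int = Field(default=15, ge=1)
    n_mc_fisher: int = Field(default=100_000, ge=100)
    pool_tau_scale: Literal["log", "sd"] = "log"
    se_aggregate: Literal["median", "mean"] = "median"
    complete_case: bool = False
    make_figures: bool = False
    out_dir: str = "out"
    seed: int = 0

    @model_validator(mode="after")
    def _check_source(self) -> "PipelineConfig":
        if self.sim is None and self.cohort_path is None:
            # default: simulate at study scale
            self.sim = SimConfig()
        if (self.cohort_path is None) != (self.centres_path is None):
            raise ConfigurationError(
                "cohort_path and centres_path must be given together"
            )
        return self


def load_config(path: str | Path, kind: str = "pipeline"):
    """Load a :class:`SimConfig` or :class:`PipelineConfig` from YAML/JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    cls = SimConfig if kind == "sim" else PipelineConfig
    try:
        return cls.model_validate(data)
    except ValidationError as exc:
        raise ConfigurationError(str(exc)) from exc


def dump_schemas(directory: str | Path) -> None:
    """Write the JSON schemas for the shipped config models."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, cls in (("sim_config", SimConfig), ("pipeline_config", PipelineConfig)):
        (directory / f"{name}.schema.json").write_text(
            json.dumps(cls.model_json_schema(), indent=2, sort_keys=True) + "\n"
        )
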