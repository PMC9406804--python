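"""Run configuration: a validated, versioned schema for simulation runs.

Defaults are the published model constants: D = 0.004/yr, mean drift
0.051/yr, log-normal starting supply (mu = 12.686, sigma = 0.497), menopause
threshold 1,000 follicles, monthly grid, 10^4 subjects, homogeneous drift
(c = 0).  Configs are JSON (YAML accepted as a convenience) and round-trip
exactly through serialisation.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, model_validator

from .first_passage import ContinuousParams
from .population import DriftSchedule, InterventionEvent, SupplyDistribution

SCHEMA_VERSION = 1


class InterventionConfig(BaseModel):
    age: float = Field(ge=0)
    surviving_fraction: float = Field(ge=0.0, le=1.0)


class RunConfig(BaseModel):
    """All tunable model and run parameters, with the published defaults."""

    schema_version: int = SCHEMA_VERSION
    D: float = Field(default=0.004, gt=0, description="diffusivity, 1/yr")
    v_bar: float = Field(default=0.051, description="mean drift, 1/yr")
    schedule_breakpoints: list[float] = Field(default_factory=list)
    schedule_values: Optional[list[float]] = Field(
        default=None,
        description="piecewise drift values (one more than breakpoints); "
        "overrides v_bar when set",
    )
    c: float = Field(default=0.0, ge=0, description="drift coefficient of variation")
    mu: float = Field(default=12.686, description="log starting-supply location")
    sigma: float = Field(default=0.497, ge=0, description="log starting-supply spread")
    x0: float = Field(default=1.0, gt=0, description="initial activity")
    L: Optional[float] = Field(
        default=None, description="death threshold; null = unbounded"
    )
    threshold: int = Field(default=1000, ge=1, description="menopause threshold, PFs")
    dt: float = Field(default=1.0 / 12.0, gt=0, description="output grid step, years")
    n_subjects: int = Field(default=10_000, ge=1)
    max_age: float = Field(default=120.0, gt=0)
    method: Literal["binomial_thinning", "per_follicle"] = "binomial_thinning"
    interventions: list[InterventionConfig] = Field(default_factory=list)
    seed: int = 0
    out_dir: str = "pfwalk_out"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.schedule_values is not None:
            if len(self.schedule_values) != len(self.schedule_breakpoints) + 1:
                raise ValueError(
                    "schedule_values must have exactly one more entry than "
                    "schedule_breakpoints"
                )
        if self.L is not None and self.L <= self.x0:
            raise ValueError("L must exceed x0")
        return self

    # --- domain-object views -------------------------------------------------

    def continuous_params(self) -> ContinuousParams:
        L = math.inf if self.L is None else self.L
        return ContinuousParams(D=self.D, V=self.v_bar, x0=self.x0, L=L)

    def drift_schedule(self) -> DriftSchedule:
        if self.schedule_values is None:
            return DriftSchedule.constant(self.v_bar)
        return DriftSchedule(
            tuple(self.schedule_breakpoints), tuple(self.schedule_values)
        )

    def supply_distribution(self) -> SupplyDistribution:
        return SupplyDistribution(mu=self.mu, sigma=self.sigma)

    def intervention_events(self) -> tuple:
        return tuple(
            InterventionEvent(ev.age, ev.surviving_fraction)
            for ev in self.interventions
        )

    # --- serialisation -------------------------------------------------------

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.model_validate(data)

    def to_file(self, path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")
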