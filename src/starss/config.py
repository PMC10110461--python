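"""Run configuration: validated, serializable, embedded in every output."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .photophysics import FluorophoreModel, RotorModel
from .schemes import DetectorPair
from .sizes import EnvironmentParams
from .sphere import SphereGrid

__all__ = ["RunConfig", "load_config"]


class RunConfig(BaseModel):
    """One simulation run; unknown keys are rejected (strict mode)."""

    model_config = ConfigDict(extra="forbid")

    scheme: Literal["method1", "method2", "method3"] = "method1"
    fluorophore: str = "rsEGFP2"
    diameter_nm: Optional[float] = Field(default=None, gt=0)
    tau_us: Optional[float] = Field(default=None, gt=0)
    static_fraction: float = Field(default=0.0, ge=0.0, le=1.0)
    temperature_K: float = Field(default=293.0, gt=0)
    viscosity_cP: float = Field(default=1.0, gt=0)
    g_factor: float = Field(default=1.0, gt=0)
    background_rate: float = Field(default=0.0, ge=0)
    dark_rate: float = Field(default=0.0, ge=0)
    cycles: int = Field(default=1, ge=1)
    seed: int = 0
    mode: Literal["expectation", "poisson"] = "poisson"
    bin_width_us: float = Field(default=2.0, gt=0)
    probe_duration_ms: float = Field(default=1.0, gt=0)
    delays_us: Optional[list[float]] = None  # scheme 3 only
    on_fraction: Optional[float] = Field(default=None, gt=0, lt=1)
    grid_n_theta: int = Field(default=64, ge=8)
    grid_n_phi: int = Field(default=128, ge=16)

    @model_validator(mode="after")
    def _check_rotor(self):
        if (self.diameter_nm is None) == (self.tau_us is None):
            raise ValueError("give exactly one of diameter_nm or tau_us")
        return self

    # -- builders -------------------------------------------------------
    def environment(self) -> EnvironmentParams:
        return EnvironmentParams(self.temperature_K, self.viscosity_cP * 1e-3)

    def rotor(self) -> RotorModel:
        if self.tau_us is not None:
            return RotorModel(
                rotational_correlation_time=self.tau_us * 1e-6,
                static_fraction=self.static_fraction,
            )
        return RotorModel.from_diameter(
            self.diameter_nm * 1e-9, self.environment(), self.static_fraction
        )

    def fluorophore_model(self) -> FluorophoreModel:
        return FluorophoreModel.from_preset(self.fluorophore)

    def detector(self) -> DetectorPair:
        return DetectorPair(self.g_factor, self.background_rate, self.dark_rate)

    def grid(self) -> SphereGrid:
        return SphereGrid(self.grid_n_theta, self.grid_n_phi)


def load_config(path: str | Path, overrides: dict | None = None) -> RunConfig:
    """Load a YAML or JSON config file; ``overrides`` take precedence."""
    path = Path(path)
    data = (
        json.loads(path.read_text())
        if path.suffix == ".json"
        else yaml.safe_load(path.read_text())
    ) or {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
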