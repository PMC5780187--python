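"""Validated run configuration: physical constants, gains, run settings.

A run configuration is a flat JSON file (sections as nested objects are also
accepted) validated with pydantic; omitted fields fall back to the study
defaults (Ts = 1/1600 s, d_wall = 0.20 m, g = 9.81 m/s^2, halteres PI gains
7 / 0.3, forward-OF setpoint 0.04).  Unknown keys are rejected so typos
cannot silently change a run, and every run echoes its effective
configuration to the output directory.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import ControllerGains, SimConfig

__all__ = ["RunConfig", "load_config"]


class SimSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    d_wall: float = Field(0.20, gt=0)
    box_height: float = Field(0.40, gt=0)
    g: float = Field(9.81, gt=0)
    ts: float = Field(1.0 / 1600.0, gt=0)
    onset_min: float = Field(0.075, gt=0)
    onset_max: float = Field(0.150, gt=0)
    horizon: float = Field(3.0, gt=0)

    def to_sim_config(self, seed: int) -> SimConfig:
        return SimConfig(
            d_wall=self.d_wall, box_height=self.box_height, g=self.g,
            ts=self.ts, onset_window=(self.onset_min, self.onset_max),
            horizon=self.horizon, seed=seed,
        )


class GainsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    kp_h: float = 7.0
    ki_h: float = 0.3
    kp_v: float = 5.0
    kd_v: float = 0.3
    tau_d: float = Field(0.01, gt=0)
    omega_x_setpoint: float = 0.04
    actuator_lag: float = Field(0.002, gt=0)
    kp_theta: float = 0.0
    kd_theta: float = 0.0
    kp_wz: float = 0.0
    ki_wz: float = 0.0

    def to_gains(self) -> ControllerGains:
        return ControllerGains(**self.model_dump())


class RunConfig(BaseModel):
    """Top-level configuration for any pipeline run."""

    model_config = ConfigDict(extra="forbid")

    sim: SimSection = Field(default_factory=SimSection)
    gains: GainsSection = Field(default_factory=GainsSection)
    variant: str = "basic"
    ensemble_size: int = Field(150, ge=1)
    estimation_mode: bool = False
    outdir: str = "results"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.variant not in ("basic", "improved"):
            raise ValueError("variant must be 'basic' or 'improved'")
        if not (0 < self.sim.onset_min <= self.sim.onset_max < self.sim.horizon):
            raise ValueError("onset window must lie within (0, horizon)")
        if self.estimation_mode:
            if not 0 <= self.gains.kp_v <= 20:
                raise ValueError("kp_v outside the estimation range [0, 20]")
            if not 0 <= self.gains.kd_v <= 2:
                raise ValueError("kd_v outside the estimation range [0, 2]")
        return self

    def sim_config(self) -> SimConfig:
        return self.sim.to_sim_config(self.seed)

    def controller_gains(self) -> ControllerGains:
        return self.gains.to_gains()

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.model_dump(), indent=1))


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration; an empty file (or empty
    object) yields all defaults."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text().strip()
    data = json.loads(text) if text else {}
    return RunConfig.model_validate(data)
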