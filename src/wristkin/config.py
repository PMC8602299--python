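"""Run configuration schema (validated JSON; unknown keys rejected)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .chain import LimbModel
from .errors import ConfigError
from .imu import FilterConfig


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class LimbConfig(_Strict):
    """Measured segment lengths (cm) and nominal sensor mounting axes."""

    L_arm_cm: float = Field(gt=0)
    L_fa_cm: float = Field(gt=0)
    nominal_axis_arm: Tuple[float, float, float] = (1.0, 0.0, 0.0)
    nominal_axis_fa: Tuple[float, float, float] = (1.0, 0.0, 0.0)

    def to_model(self) -> LimbModel:
        return LimbModel(
            L_arm=self.L_arm_cm,
            L_fa=self.L_fa_cm,
            nominal_axis_arm=np.asarray(self.nominal_axis_arm),
            nominal_axis_fa=np.asarray(self.nominal_axis_fa),
        )


class FilterSettings(_Strict):
    run_gain: float = Field(default=0.1, ge=0)
    init_gain: float = Field(default=2.5, ge=0)
    rest_duration: float = Field(default=5.0, gt=0)
    prepend_total: float = Field(default=30.0, gt=0)
    mag_yaw_only: bool = True

    def to_config(self) -> FilterConfig:
        return FilterConfig(
            run_gain=self.run_gain,
            init_gain=self.init_gain,
            rest_duration=self.rest_duration,
            prepend_total=self.prepend_total,
            mag_yaw_only=self.mag_yaw_only,
        )


class MetricSettings(_Strict):
    speed_threshold: float = Field(default=2.0, gt=0)
    min_hold: float = Field(default=1.0, gt=0)
    diff_window: int = Field(default=7, ge=5)


class RunConfig(_Strict):
    """Everything needed to reproduce a tracking run from its input files."""

    mode: Literal["imu", "pose"]
    arm_stream: str
    fa_stream: str
    rest_window: Tuple[float, float]
    limb: LimbConfig
    fe_window: Optional[Tuple[float, float]] = None
    mag_calibration_arm: Optional[str] = None
    mag_calibration_fa: Optional[str] = None
    native_frame: Literal["y_up", "z_up"] = "y_up"
    max_gap: float = Field(default=0.2, gt=0)
    resample_rate: float = Field(default=100.0, gt=0)
    filter: FilterSettings = Field(default_factory=FilterSettings)
    metrics: MetricSettings = Field(default_factory=MetricSettings)
    out_dir: str = "."
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path) as fh:
                data = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            return cls.model_validate(data)
        except ValidationError as exc:
            raise ConfigError(f"invalid run config {path}:\n{exc}") from exc

    def resolve_path(self, p: str, base: Path) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q
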