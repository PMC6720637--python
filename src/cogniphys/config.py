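"""Run configuration: every tunable of the toolkit with units and defaults.

Unknown keys are rejected so typos in a YAML file fail loudly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict


class FilterSpec(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lowpass_hz: float | None = None
    highpass_hz: float | None = None
    notch_hz: float | None = None
    order: int = 2


class RunConfig(BaseModel):
    """All tunables, each with its ledger default."""

    model_config = ConfigDict(extra="forbid")

    # gaze event detection
    d_max: float = 1.0  # deg, fixation dispersion threshold
    min_fix_duration: float = 0.1  # s
    v_threshold: float = 30.0  # deg/s, saccade velocity threshold
    saccade_dur_bounds: tuple[float, float] = (0.03, 0.08)  # s
    long_fix_threshold: float = 0.5  # s, explore/exploit "long" fixation
    blink_max_gap: float = 0.5  # s, invalid runs longer are tracking loss
    pupil_band: tuple[float, float] = (2.0, 6.0)  # Hz

    # cardiac cleaning / spectra
    nn_bounds: tuple[float, float] = (300.0, 2000.0)  # ms
    nn_max_rel_jump: float = 0.3
    psd_method: Literal["lomb", "welch"] = "lomb"
    poincare_window: float = 30.0  # s

    # fuzzy calibration
    mf_spread_rule: Literal["half_nn"] = "half_nn"
    calibration_seed: int = 0
    calibration_maxiter: int = 200
    calibration_tol: float = 1e-8

    # streaming inference epochs
    window_s: float = 60.0
    step_s: float = 10.0

    # signal conditioning
    filter: FilterSpec = FilterSpec()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        s = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if path is not None:
            Path(path).write_text(s)
        return s
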