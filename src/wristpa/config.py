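"""Pipeline configuration with published defaults.

Defaults follow the source protocol where one exists (50 Hz sampling,
5-s epochs, 0.03/0.1/0.4 g cut-offs, 60-min non-wear windows, 600-min
valid-day threshold, 10-h activity window, 46/64/100% relative bands);
non-wear step/thresholds and the MET oxygen cost are conventional values
exposed as keys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

from wristpa.errors import ConfigError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # raw processing
    fs: float = 50.0
    epoch_length: float = 5.0
    truncate: str = "sample"  # sample | epoch
    calibrate: bool = True
    # non-wear detection
    nonwear_window_min: float = 60.0
    nonwear_step_min: float = 15.0
    nonwear_sd_thresh: float = 0.013
    nonwear_range_thresh: float = 0.050
    nonwear_min_axes: int = 2
    # classification
    cutoff_light: float = 0.03
    cutoff_moderate: float = 0.1
    cutoff_vigorous: float = 0.4
    min_bout_min: float = 10.0
    bout_tolerance_epochs: int = 0
    min_wear_minutes: float = 600.0
    # relative intensity
    met_value: float = 3.5
    band_lpa_upper: float = 46.0
    band_mpa_upper: float = 64.0
    band_capacity: float = 100.0
    met_anchors: tuple = (2.0, 3.0, 6.0)
    # active window
    window_length_h: float = 10.0
    window_metric: str = "tpa_minutes"
    window_wrap: bool = False
    histogram_bin_min: float = 30.0
    # models
    model_outcomes: tuple = ("tpa", "mvpa")
    model_weights: str = "off"  # off | by_factor_level
    # simulation scale
    sim_heart_subjects: int = 2
    sim_health_subjects: int = 2
    sim_days: int = 14
    sim_start_date: str = "2019-06-03"
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.epoch_length <= 0:
            raise ConfigError("fs and epoch_length must be positive")
        if not (0 < self.cutoff_light < self.cutoff_moderate < self.cutoff_vigorous):
            raise ConfigError("cut-offs must be increasing and positive")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Parse a key=value text file; '#' starts a comment."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(value, fields[key].type, key)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["met_anchors"] = list(self.met_anchors)
        d["model_outcomes"] = list(self.model_outcomes)
        return d


def _coerce(value: str, ftype, key: str):
    ftype = str(ftype)
    if "bool" in ftype:
        if value.lower() in ("1", "true", "yes", "on"):
            return True
        if value.lower() in ("0", "false", "no", "off"):
            return False
        raise ConfigError(f"cannot parse boolean {key}={value!r}")
    if "int" in ftype:
        return int(value)
    if "float" in ftype:
        return float(value)
    if "tuple" in ftype:
        parts = [p.strip() for p in value.split(",") if p.strip()]
        try:
            return tuple(float(p) for p in parts)
        except ValueError:
            return tuple(parts)
    return value
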