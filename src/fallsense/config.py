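"""Configuration for the whole pipeline.

Every numeric constant the pipeline depends on lives in one of the dataclasses
below, so a single YAML file can override any of them.  Defaults encode the
device characteristics of the chest-worn unit (BMX055 IMU + BMP280 barometer,
100 Hz) and the published decision parameters: a 0.1 s decision tick, a 1.5 s
barometric observation window, and the fall rule "change in G value > 600 LSB
and change in pressure > 3 Pa".
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

# Table-of-record sensor scale factors (BMX055 / BMP280 datasheet values).
ACC_LSB_PER_G = 512.0
GYRO_LSB_PER_DPS = 32.8
MAG_LSB_PER_UT = 3.3
PRESS_LSB_PER_PA = 6.0

PRESSURE_MIN_PA = 30_000.0   # 300 hPa
PRESSURE_MAX_PA = 110_000.0  # 1100 hPa
ACC_RANGE_G = 4.0

STANDARD_PRESSURE_PA = 101_325.0


@dataclass
class FusionConfig:
    """Orientation / altitude fusion parameters."""

    beta: float = 0.1                 # Madgwick gain, dimensionless
    decision_tick_s: float = 0.1      # feature-frame cadence
    dg_window_s: float = 1.0          # trailing window for max-min resultant G
    dp_window_s: float = 1.5          # trailing window for pressure difference
    kalman_q_m2: float = 1e-4         # altitude process noise per step
    kalman_r_m2: float = 0.01         # altitude measurement noise (~±1 m baro)
    p_ref_window_s: float = 0.5       # initial span averaged for reference pressure


@dataclass
class FsmConfig:
    """Behavior-state classifier and state-machine parameters."""

    lying_angle_deg: float = 60.0     # |lean| beyond this counts as lying
    lying_sustain_s: float = 1.0
    chair_band_m: tuple[float, float] = (0.25, 0.7)  # |Δaltitude| band for sit/stand
    band_sustain_ticks: int = 3       # debounce for altitude-band labels
    walk_peak_g: float = 1.15         # step peaks must exceed this
    walk_min_peaks: int = 3
    walk_window_s: float = 2.0
    walk_cadence_hz: tuple[float, float] = (1.5, 2.5)
    init_walk_s: float = 3.0          # walking required to leave INITIAL
    dwell_s: float = 1.0              # quiescence to resolve transient states


@dataclass
class DetectorConfig:
    """Fall rule, direction and impact parameters."""

    dg_threshold_lsb: float = 600.0   # change in resultant G, raw counts
    dp_threshold_pa: float = 3.0      # change in pressure over the 1.5 s window
    accel_sensitivity_lsb_per_g: float = ACC_LSB_PER_G
    decision_tick_s: float = 0.1
    direction_angle_min_deg: float = 20.0
    direction_delay_s: float = 0.5    # sample orientation this long after impact
    refractory_s: float = 3.0
    weightless_g: float = 0.6         # dip below this marks the weightless phase


@dataclass
class AlertConfig:
    verify_delay_s: float = 30.0      # two-stage confirmation timer


@dataclass
class SimConfig:
    """Synthetic-trial generator defaults (sensor noise per the device spec)."""

    rate_hz: float = 100.0
    acc_noise_g: float = 0.01
    gyro_noise_dps: float = 0.5
    pressure_noise_pa: float = 6.0    # 0.06 hPa
    p_ref_pa: float = STANDARD_PRESSURE_PA
    chair_drop_m: float = 0.45
    walk_amp_g: float = 0.3
    walk_freq_hz: float = 2.0


@dataclass
class PipelineConfig:
    fusion: FusionConfig = field(default_factory=FusionConfig)
    fsm: FsmConfig = field(default_factory=FsmConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    alert: AlertConfig = field(default_factory=AlertConfig)
    sim: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        for section_name, section in d.items():
            target = getattr(cfg, section_name, None)
            if target is None or not dataclasses.is_dataclass(target):
                raise KeyError(f"unknown config section: {section_name!r}")
            names = {f.name for f in dataclasses.fields(target)}
            for key, value in (section or {}).items():
                if key not in names:
                    raise KeyError(f"unknown config key: {section_name}.{key}")
                if isinstance(getattr(target, key), tuple):
                    value = tuple(value)
                setattr(target, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
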