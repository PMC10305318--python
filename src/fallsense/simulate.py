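"""Seeded synthetic-trace generator for fall protocols and daily activities.

No public dataset exists for the chest-worn device, so trials are synthesized
from kinematic scripts that mirror the published fall protocols: the subject
stands still, walks about ten steps (which also initializes the state
machine), then falls forward / backward / leftward / rightward onto a
cushion, starting from sitting (category A), standing (B), or mid stand-up
(C).  Matched non-fall activities of daily living (sitting down — also
quickly, standing up, walking, lying down deliberately) provide the negative
trials, deliberately including the movements a fall detector most easily
confuses.

Each script drives four mutually consistent channels: the resultant-G
profile, the lean-angle trajectory (whose roll/pitch signs encode the fall
direction), the chest height, and the barometric pressure obtained from the
height through the inverse hypsometric conversion.  A fall contributes a
weightlessness dip (0.25-0.45 g), an impact peak (2.2-3.6 g), a lean ramp to
lying, and a chest-height drop; Gaussian sensor noise then emulates the
device (acc sigma 0.01 g, gyro sigma 0.5 deg/s, pressure sigma 6 Pa) and the
trace is emitted at 100 Hz.  Ground-truth labels are generated from the same
script object, so trace and labels cannot disagree.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import ACC_RANGE_G, SimConfig
from .fall_detection import FallDirection
from .fusion import altitude_to_pressure
from .signal_io import SensorLog, write_sensor_log

CATEGORIES = ("A", "B", "C")   # fall from sitting / while standing / while standing up
DIRECTIONS = ("forward", "backward", "left", "right")

_ADL_KINDS_BY_CATEGORY: dict[str, tuple[str, ...]] = {
    "A": ("sit_down", "sit_down_quick"),
    "B": ("walk_long", "lie_down"),
    "C": ("stand_up_cycle", "sit_down_quick"),
}


@dataclass(frozen=True)
class TrialSpec:
    """Description of one simulated trial."""

    category: str                  # A | B | C | ADL
    direction: str                 # forward|backward|left|right|none
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES + ("ADL",):
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "ADL":
            if self.direction != "none":
                raise ValueError("ADL trials carry no fall direction")
        elif self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def name(self) -> str:
        kind = self.params.get("adl_kind", self.direction)
        return f"{self.category}_{kind}_{self.seed}"


@dataclass
class GroundTruth:
    """Labeled event timeline generated alongside the trace."""

    events: list[tuple[float, str]]
    fall_time: float | None = None
    fall_direction: FallDirection | None = None
    prefall_state: str | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "events": self.events,
                "fall_time": self.fall_time,
                "fall_direction": None if self.fall_direction is None else self.fall_direction.value,
                "prefall_state": self.prefall_state,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            events=[(float(t), lab) for t, lab in d["events"]],
            fall_time=d["fall_time"],
            fall_direction=None if d["fall_direction"] is None else FallDirection(d["fall_direction"]),
            prefall_state=d["prefall_state"],
        )


# ---------------------------------------------------------------------------
# Kinematic segments
# ---------------------------------------------------------------------------

def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass
class _Segment:
    kind: str
    duration: float
    params: dict = field(default_factory=dict)


@dataclass
class _ChannelState:
    """Kinematic state carried across segments."""

    height: float = 0.0        # chest height relative to trace start, m
    roll: float = 0.0          # deg
    pitch: float = 0.0         # deg


def _direction_lean(direction: str, angle: float) -> tuple[float, float]:
    """(roll, pitch) of a settled lying posture after a fall in ``direction``."""
    return {
        "forward": (0.0, +angle),
        "backward": (0.0, -angle),
        "right": (+angle, 0.0),
        "left": (-angle, 0.0),
    }[direction]


def _render_segment(
    seg: _Segment, state: _ChannelState, rate: float, cfg: SimConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, _ChannelState]:
    """Returns (gmag, height, roll, pitch) sample arrays and the end state."""
    n = max(1, int(round(seg.duration * rate)))
    tau = np.arange(n) / rate
    ones = np.ones(n)
    g = ones.copy()
    h = ones * state.height
    roll = ones * state.roll
    pitch = ones * state.pitch
    p = seg.params

    if seg.kind in ("stance", "sit", "lie_still"):
        pass
    elif seg.kind == "walk":
        amp = p.get("amp", cfg.walk_amp_g)
        freq = p.get("freq", cfg.walk_freq_hz)
        g = 1.0 + amp * np.sin(2.0 * math.pi * freq * tau)
        h = h + 0.02 * np.sin(2.0 * math.pi * freq * tau)   # slight bob
    elif seg.kind in ("sit_down", "stand_up"):
        drop = p.get("drop", cfg.chair_drop_m)
        sign = -1.0 if seg.kind == "sit_down" else +1.0
        wobble = p.get("wobble", 0.15)
        h = state.height + sign * drop * _smoothstep(tau / seg.duration)
        g = 1.0 - sign * wobble * np.sin(2.0 * math.pi * tau / seg.duration)
    elif seg.kind == "lie_down":
        # deliberate, slow lying down
        drop = p.get("drop", 1.0)
        angle = p.get("angle", 80.0)
        direction = p.get("direction", "backward")
        r_t, p_t = _direction_lean(direction, angle)
        s = _smoothstep(tau / seg.duration)
        h = state.height - drop * s
        roll = state.roll + (r_t - state.roll) * s
        pitch = state.pitch + (p_t - state.pitch) * s
        g = 1.0 + 0.1 * np.sin(2.0 * math.pi * tau / seg.duration)
    elif seg.kind == "fall":
        dip = p["dip"]
        peak = p["peak"]
        angle = p["lean"]
        direction = p["direction"]
        h_target = p["h_target"]
        # resultant-G keypoints: free-fall dip then impact spike then settle
        kp_t = np.array([0.0, 0.15, 0.30, 0.45, 0.55, 0.65, 0.80, seg.duration])
        kp_g = np.array([1.0, 0.80, dip, 0.60, peak, 1.30, 1.0, 1.0])
        g = np.interp(tau, kp_t, kp_g)
        s_lean = _smoothstep((tau - 0.10) / 0.55)
        r_t, p_t = _direction_lean(direction, angle)
        roll = state.roll + (r_t - state.roll) * s_lean
        pitch = state.pitch + (p_t - state.pitch) * s_lean
        s_h = _smoothstep((tau - 0.15) / 0.55)
        h = state.height + (h_target - state.height) * s_h
    else:  # pragma: no cover
        raise ValueError(f"unknown segment kind {seg.kind!r}")

    end = _ChannelState(height=float(h[-1]), roll=float(roll[-1]), pitch=float(pitch[-1]))
    return g, h, roll, pitch, end


# segment kind -> behavior label used in the ground-truth timeline
_SEGMENT_LABELS = {
    "stance": "STANDING",
    "sit": "SITTING",
    "lie_still": "LYING",
    "walk": "WALKING",
    "sit_down": "SITTING_DOWN",
    "stand_up": "STANDING_UP",
    "lie_down": "LYING",
    "fall": "FALLING",
}

_FALL_PEAK_TAU = 0.55   # impact-peak offset inside a fall segment, s


# ---------------------------------------------------------------------------
# Scripts
# ---------------------------------------------------------------------------

def _build_script(spec: TrialSpec, rng: np.random.Generator, cfg: SimConfig):
    """Compose the segment list for a trial spec; kinematic magnitudes are
    drawn per trial from physiologically plausible ranges."""
    chest = rng.uniform(1.15, 1.35)          # standing chest height, m
    h_lying = -(chest - 0.15)                # chest height when lying, rel. start
    chair = rng.uniform(0.9, 1.1) * cfg.chair_drop_m
    walk_amp = rng.uniform(0.95, 1.15) * cfg.walk_amp_g
    walk_freq = rng.uniform(0.9, 1.1) * cfg.walk_freq_hz
    dip = rng.uniform(0.25, 0.45)
    peak = rng.uniform(2.2, 3.6)
    lean = rng.uniform(70.0, 85.0)

    def fall_seg(direction: str) -> _Segment:
        return _Segment("fall", 1.5, {
            "dip": dip, "peak": peak, "lean": lean,
            "direction": direction, "h_target": h_lying,
        })

    walk = _Segment("walk", 4.5, {"amp": walk_amp, "freq": walk_freq})
    init = [_Segment("stance", 1.5), walk]

    if spec.category == "A":
        segments = init + [
            _Segment("stance", 1.5),
            _Segment("sit_down", 1.5, {"drop": chair}),
            _Segment("sit", 3.0),
            fall_seg(spec.direction),
            _Segment("lie_still", 2.0),
        ]
        prefall = "SITTING"
    elif spec.category == "B":
        segments = [
            _Segment("stance", 1.5),
            _Segment("walk", 5.0, {"amp": walk_amp, "freq": walk_freq}),
            _Segment("stance", 1.0),
            fall_seg(spec.direction),
            _Segment("lie_still", 2.0),
        ]
        prefall = "STANDING"
    elif spec.category == "C":
        segments = init + [
            _Segment("stance", 1.5),
            _Segment("sit_down", 1.5, {"drop": chair}),
            _Segment("sit", 3.0),
            _Segment("stand_up", 1.0, {"drop": 0.30}),   # interrupted mid-rise
            fall_seg(spec.direction),
            _Segment("lie_still", 2.0),
        ]
        prefall = "STANDING_UP"
    else:  # ADL
        kind = spec.params.get("adl_kind", "sit_down")
        if kind == "sit_down":
            segments = init + [
                _Segment("stance", 1.5),
                _Segment("sit_down", 1.5, {"drop": chair}),
                _Segment("sit", 3.0),
                _Segment("stand_up", 1.5, {"drop": chair}),
                _Segment("stance", 2.0),
            ]
        elif kind == "sit_down_quick":
            segments = init + [
                _Segment("stance", 1.5),
                _Segment("sit_down", 0.8, {"drop": chair, "wobble": 0.35}),
                _Segment("sit", 3.0),
                _Segment("stand_up", 1.5, {"drop": chair}),
                _Segment("stance", 2.0),
            ]
        elif kind == "stand_up_cycle":
            segments = init + [
                _Segment("stance", 1.0),
                _Segment("sit_down", 1.5, {"drop": chair}),
                _Segment("sit", 3.0),
                _Segment("stand_up", 1.2, {"drop": chair}),
                _Segment("stance", 2.5),
            ]
        elif kind == "sit_cycle":
            segments = init + [
                _Segment("stance", 1.5),
                _Segment("sit_down", 1.5, {"drop": chair}),
                _Segment("sit", 3.0),
                _Segment("stand_up", 1.5, {"drop": chair}),
                _Segment("stance", 3.5),
                _Segment("sit_down", 1.5, {"drop": chair}),
                _Segment("sit", 3.0),
            ]
        elif kind == "walk_long":
            segments = [
                _Segment("stance", 1.5),
                _Segment("walk", 6.0, {"amp": walk_amp, "freq": walk_freq}),
                _Segment("stance", 1.5),
                _Segment("walk", 2.0, {"amp": walk_amp, "freq": walk_freq}),
                _Segment("stance", 1.5),
            ]
        elif kind == "lie_down":
            segments = init + [
                _Segment("stance", 1.0),
                _Segment("lie_down", 2.5, {"drop": chest - 0.15,
                                           "direction": "backward"}),
                _Segment("lie_still", 3.0),
            ]
        else:
            raise ValueError(f"unknown ADL kind {kind!r}")
        prefall = None
    return segments, prefall


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------

def simulate_trial(
    spec: TrialSpec, config: SimConfig | None = None
) -> tuple[SensorLog, GroundTruth]:
    """Render one trial to a 100 Hz sensor log plus its ground truth."""
    cfg = config or SimConfig()
    for key in spec.params:
        if key not in ("adl_kind",):
            raise ValueError(f"unknown trial parameter {key!r}")
    rng = np.random.default_rng(spec.seed)
    segments, prefall = _build_script(spec, rng, cfg)

    gs, hs, rolls, pitches = [], [], [], []
    events: list[tuple[float, str]] = []
    fall_time = None
    state = _ChannelState()
    t_cursor = 0.0
    for seg in segments:
        g, h, r, p, state = _render_segment(seg, state, cfg.rate_hz, cfg)
        gs.append(g)
        hs.append(h)
        rolls.append(r)
        pitches.append(p)
        events.append((round(t_cursor, 6), _SEGMENT_LABELS[seg.kind]))
        if seg.kind == "fall":
            fall_time = t_cursor + _FALL_PEAK_TAU
        t_cursor += seg.duration

    g = np.concatenate(gs)
    h = np.concatenate(hs)
    roll = np.radians(np.concatenate(rolls))
    pitch = np.radians(np.concatenate(pitches))
    n = len(g)
    t = np.arange(n) / cfg.rate_hz

    # up-direction in the body frame from the lean trajectory (unit by design)
    ux = -np.sin(roll) * np.cos(pitch)
    uy = np.cos(roll) * np.cos(pitch)
    uz = -np.sin(pitch)
    acc = np.stack([ux * g, uy * g, uz * g], axis=1)
    acc += rng.normal(0.0, cfg.acc_noise_g, acc.shape)
    acc = np.clip(acc, -ACC_RANGE_G, ACC_RANGE_G)

    # body rates consistent with the lean trajectory (deg/s)
    dt = 1.0 / cfg.rate_hz
    gyro = np.zeros((n, 3))
    gyro[:, 0] = np.degrees(np.gradient(pitch, dt))
    gyro[:, 2] = -np.degrees(np.gradient(roll, dt))
    gyro += rng.normal(0.0, cfg.gyro_noise_dps, gyro.shape)

    pressure = altitude_to_pressure(h, cfg.p_ref_pa)
    pressure = np.asarray(pressure) + rng.normal(0.0, cfg.pressure_noise_pa, n)

    log = SensorLog(
        t=t, acc=acc, gyro=gyro, pressure=pressure,
        rate_hz=cfg.rate_hz,
        meta={"trial": spec.name, "category": spec.category,
              "direction": spec.direction, "seed": str(spec.seed),
              "units": "physical", "rate_hz": f"{cfg.rate_hz:g}",
              "synthetic": "true"},
    )
    log.validate()
    truth = GroundTruth(
        events=events,
        fall_time=fall_time,
        fall_direction=None if spec.category == "ADL"
        else FallDirection(spec.direction.upper()
                           if spec.direction in ("left", "right")
                           else {"forward": "FORWARD", "backward": "BACKWARD"}[spec.direction]),
        prefall_state=prefall,
    )
    return log, truth


@dataclass
class Trial:
    spec: TrialSpec
    log: SensorLog
    truth: GroundTruth


def simulate_experiment(
    n_per_cell: int, seed: int, config: SimConfig | None = None
) -> list[Trial]:
    """Balanced grid: ``n_per_cell`` falls per (category x direction) cell
    plus the same number of matched non-fall trials per category.

    Per-trial seeds are derived deterministically from ``seed``.
    """
    if n_per_cell < 1:
        raise ValueError("n_per_cell must be >= 1")
    cfg = config or SimConfig()
    master = np.random.default_rng(seed)
    trials: list[Trial] = []
    for category in CATEGORIES:
        for direction in DIRECTIONS:
            for _ in range(n_per_cell):
                spec = TrialSpec(
                    category=category, direction=direction,
                    seed=int(master.integers(0, 2**31 - 1)),
                )
                log, truth = simulate_trial(spec, cfg)
                trials.append(Trial(spec, log, truth))
        # matched negatives: one per fall trial, cycling the confusable ADLs
        kinds = _ADL_KINDS_BY_CATEGORY[category]
        for i in range(n_per_cell * len(DIRECTIONS)):
            spec = TrialSpec(
                category="ADL", direction="none",
                seed=int(master.integers(0, 2**31 - 1)),
                params={"adl_kind": kinds[i % len(kinds)]},
            )
            log, truth = simulate_trial(spec, cfg)
            trial = Trial(spec, log, truth)
            trial.spec.params["matched_category"] = category
            trials.append(trial)
    return trials


def write_trial(trial: Trial, out_dir: str | Path) -> tuple[Path, Path]:
    """Write one trial as a CSV log plus a JSON ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matched = trial.spec.params.get("matched_category", "")
    stem = (f"{matched}_" if matched else "") + trial.spec.name
    log_path = out_dir / f"{stem}.csv"
    truth_path = out_dir / f"{stem}.truth.json"
    write_sensor_log(trial.log, log_path)
    truth_path.write_text(trial.truth.to_json() + "\n", encoding="utf-8")
    return log_path, truth_path


def write_experiment(trials: Sequence[Trial], out_dir: str | Path) -> Path:
    """Write all trials plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = []
    for trial in trials:
        log_path, truth_path = write_trial(trial, out_dir)
        rows.append(
            {
                "file": log_path.name,
                "truth": truth_path.name,
                "category": trial.spec.category,
                "matched_category": trial.spec.params.get("matched_category", ""),
                "direction": trial.spec.direction,
                "adl_kind": trial.spec.params.get("adl_kind", ""),
                "seed": trial.spec.seed,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
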