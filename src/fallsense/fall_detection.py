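"""Threshold fall rule, direction, impact magnitude and pre-fall context.

A fall is declared when, within the same decision tick, the change in the
resultant G value over the trailing window exceeds 600 raw accelerometer
counts (600/512 ~ 1.17 g) AND the pressure change over the trailing 1.5 s
window exceeds 3 Pa (~0.25 m of altitude).  Both inequalities are strict and
both must hold: the G condition captures the weightlessness dip plus impact
peak, the pressure condition the chest-height drop, so neither brisk
arm/torso movement nor an elevator ride alone can trigger it.

The fall direction is read from the settled post-impact orientation: right
lean -> roll > 0, forward lean -> pitch > 0, dominant axis wins (ties go to
the pitch axis).  Impact magnitude is the G peak following the weightless
minimum.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from enum import Enum
from typing import TYPE_CHECKING, Sequence

import numpy as np

from .config import DetectorConfig
from .fusion import FeatureFrame

if TYPE_CHECKING:  # pragma: no cover
    from .behavior_fsm import BehaviorState, FsmRun

logger = logging.getLogger(__name__)


class FallDirection(str, Enum):
    FORWARD = "FORWARD"
    BACKWARD = "BACKWARD"
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    INDETERMINATE = "INDETERMINATE"


@dataclass
class FallEvent:
    """One detected fall."""

    t_impact: float
    direction: FallDirection
    impact_peak_g: float
    dg_lsb: float
    dp_pa: float
    prefall_state: "BehaviorState | None" = None
    t_detect: float = 0.0          # tick at which the rule fired
    no_dip_flag: bool = False      # impact peak taken without a weightless dip
    direction_flag: bool = False   # both lean angles below the dead-zone bound

    def to_json(self) -> str:
        d = {
            "t_impact": self.t_impact,
            "direction": self.direction.value,
            "impact_peak_g": self.impact_peak_g,
            "dg_lsb": self.dg_lsb,
            "dp_pa": self.dp_pa,
            "prefall_state": None if self.prefall_state is None else self.prefall_state.value,
        }
        return json.dumps(d)


def is_fall_frame(frame: FeatureFrame, config: DetectorConfig | None = None) -> bool:
    """The conjunctive threshold rule on a single feature frame.

    ``dg_window`` (g) is converted to raw counts with the accelerometer
    sensitivity before comparison.  Strict inequalities on both thresholds.
    """
    cfg = config or DetectorConfig()
    dg_lsb = frame.dg_window * cfg.accel_sensitivity_lsb_per_g
    return dg_lsb > cfg.dg_threshold_lsb and frame.dp_window > cfg.dp_threshold_pa


def classify_direction(
    roll: float, pitch: float, config: DetectorConfig | None = None
) -> FallDirection:
    """Dominant-axis sign rule on the post-fall lean angles (degrees).

    |pitch| >= |roll|: FORWARD if pitch > 0 else BACKWARD; otherwise RIGHT if
    roll > 0 else LEFT.  If both angles sit inside the dead zone the result
    is INDETERMINATE.
    """
    cfg = config or DetectorConfig()
    if max(abs(roll), abs(pitch)) < cfg.direction_angle_min_deg:
        logger.debug("direction indeterminate: |roll|=%.1f |pitch|=%.1f", roll, pitch)
        return FallDirection.INDETERMINATE
    if abs(pitch) >= abs(roll):
        return FallDirection.FORWARD if pitch > 0 else FallDirection.BACKWARD
    return FallDirection.RIGHT if roll > 0 else FallDirection.LEFT


def impact_magnitude(
    t: Sequence[float],
    g: Sequence[float],
    config: DetectorConfig | None = None,
) -> tuple[float, float, bool]:
    """Peak resultant G after the weightless phase.

    Returns ``(peak_g, t_peak, no_dip_flag)``: the maximum G between the
    weightless minimum (first dip below the weightlessness threshold) and 1 s
    after it.  Without a dip the peak is taken over the whole series and
    flagged.
    """
    cfg = config or DetectorConfig()
    t = np.asarray(t, float)
    g = np.asarray(g, float)
    if len(g) == 0:
        raise ValueError("empty G series")
    below = np.nonzero(g < cfg.weightless_g)[0]
    if below.size == 0:
        i = int(np.argmax(g))
        return float(g[i]), float(t[i]), True
    # weightless minimum: lowest G within the first sub-threshold excursion
    start = below[0]
    end = start
    while end + 1 < len(g) and g[end + 1] < cfg.weightless_g:
        end += 1
    i_min = start + int(np.argmin(g[start : end + 1]))
    sel = (t >= t[i_min]) & (t <= t[i_min] + 1.0)
    idx = np.nonzero(sel)[0]
    i_peak = idx[int(np.argmax(g[idx]))]
    return float(g[i_peak]), float(t[i_peak]), False


def detect_falls(
    frames: Sequence[FeatureFrame],
    config: DetectorConfig | None = None,
    raw_t: Sequence[float] | None = None,
    raw_g: Sequence[float] | None = None,
) -> list[FallEvent]:
    """Scan feature frames with the fall rule, at most one event per
    refractory period.

    When the raw-rate resultant G series is supplied the impact peak and
    timing are measured on it (the decision tick undersamples a sharp impact
    spike); otherwise the tick-rate ``g_value`` stream is used.
    """
    cfg = config or DetectorConfig()
    if raw_t is None or raw_g is None:
        raw_t = np.array([f.t for f in frames])
        raw_g = np.array([f.g_value for f in frames])
    else:
        raw_t = np.asarray(raw_t, float)
        raw_g = np.asarray(raw_g, float)
    events: list[FallEvent] = []
    last_fire = -np.inf
    frame_times = np.array([f.t for f in frames])
    for k, frame in enumerate(frames):
        if frame.t - last_fire < cfg.refractory_s:
            continue
        if not is_fall_frame(frame, cfg):
            continue
        last_fire = frame.t
        # impact characterization on the raw series around the firing tick
        sel = (raw_t >= frame.t - 1.5) & (raw_t <= frame.t + 1.0)
        idx = np.nonzero(sel)[0]
        peak, t_peak, no_dip = impact_magnitude(raw_t[idx], raw_g[idx], cfg)
        # orientation sampled after the body settles
        j = int(np.searchsorted(frame_times, t_peak + cfg.direction_delay_s, side="left"))
        j = min(j, len(frames) - 1)
        direction = classify_direction(frames[j].roll, frames[j].pitch, cfg)
        events.append(
            FallEvent(
                t_impact=t_peak,
                direction=direction,
                impact_peak_g=peak,
                dg_lsb=frame.dg_window * cfg.accel_sensitivity_lsb_per_g,
                dp_pa=frame.dp_window,
                t_detect=frame.t,
                no_dip_flag=no_dip,
                direction_flag=direction is FallDirection.INDETERMINATE,
            )
        )
    return events


def annotate_prefall(event: FallEvent, fsm_run: "FsmRun") -> FallEvent:
    """Attach the last non-FALLING behavior state before the detection."""
    from .behavior_fsm import BehaviorState  # late import to avoid a cycle

    prefall = BehaviorState.INITIAL
    t_ref = min(event.t_detect or event.t_impact, event.t_impact)
    for t, state in zip(fsm_run.times, fsm_run.states):
        if t >= t_ref:
            break
        if state is not BehaviorState.FALLING:
            prefall = state
    if prefall is BehaviorState.INITIAL:
        logger.debug("fall at t=%.2f with no prior state: still INITIAL", event.t_impact)
    return replace(event, prefall_state=prefall)
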