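"""Two-stage fall verification as pure timer/event logic.

Stage one: a detected fall immediately raises a PENDING alert and pushes a
first notification.  Stage two: 30 s later the wearer's behavior state is
re-checked — if they are still down (FALLING or LYING) the alert is
CONFIRMED and a second, escalated notification goes out; if they have
recovered it resolves as a false alarm.  The wearer can cancel within the
30 s window; after the deadline a cancel is rejected because escalation has
already fired.

Time is injected (plain seconds), and the notification sink is a pluggable
interface, so the whole action log is deterministic and testable.  Delivery
infrastructure (speakers, cloud messaging) is out of scope.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Protocol

from .behavior_fsm import BehaviorState
from .config import AlertConfig
from .fall_detection import FallEvent

logger = logging.getLogger(__name__)


class AlertStatus(str, Enum):
    PENDING = "PENDING"
    CONFIRMED = "CONFIRMED"
    CANCELLED = "CANCELLED"


class CancelAfterDeadlineError(Exception):
    """Cancellation arrived after the verification deadline: the escalation
    path has already been taken."""


@dataclass
class NotificationAction:
    t: float
    alert_id: int
    stage: str                     # "alert" | "escalation"
    payload: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"t": self.t, "alert_id": self.alert_id, "action": self.stage,
             "channel": "notifier", **({"payload": self.payload} if self.payload else {})}
        )


class Notifier(Protocol):
    def notify(self, action: NotificationAction) -> None: ...


class RecordingNotifier:
    """In-memory sink used in tests and offline runs."""

    def __init__(self) -> None:
        self.actions: list[NotificationAction] = []

    def notify(self, action: NotificationAction) -> None:
        self.actions.append(action)


@dataclass
class AlertRecord:
    id: int
    t_created: float
    t_deadline: float
    status: AlertStatus = AlertStatus.PENDING
    event: FallEvent | None = None


class AlertManager:
    """Owns the alert records and drives the two-stage protocol."""

    def __init__(self, notifier: Notifier | None = None,
                 config: AlertConfig | None = None) -> None:
        self.notifier = notifier
        self.config = config or AlertConfig()
        self.records: list[AlertRecord] = []
        self.queued_actions: list[NotificationAction] = []
        self._ids = itertools.count(1)

    # -- notification plumbing ------------------------------------------------
    def _emit(self, action: NotificationAction) -> None:
        if self.notifier is None:
            self.queued_actions.append(action)
            return
        try:
            self.notifier.notify(action)
        except Exception:
            logger.warning("notifier unavailable; action queued")
            self.queued_actions.append(action)

    def flush_queue(self) -> int:
        """Retry queued actions; returns how many were delivered."""
        pending, self.queued_actions = self.queued_actions, []
        delivered = 0
        for action in pending:
            before = len(self.queued_actions)
            self._emit(action)
            if len(self.queued_actions) == before:
                delivered += 1
        return delivered

    # -- protocol -------------------------------------------------------------
    def on_fall(self, event: FallEvent, t_now: float) -> AlertRecord:
        """Create a PENDING record with the 30 s deadline and push the first
        notification."""
        record = AlertRecord(
            id=next(self._ids),
            t_created=t_now,
            t_deadline=t_now + self.config.verify_delay_s,
            event=event,
        )
        self.records.append(record)
        self._emit(
            NotificationAction(
                t=t_now, alert_id=record.id, stage="alert",
                payload={"direction": event.direction.value,
                         "impact_peak_g": event.impact_peak_g},
            )
        )
        return record

    def cancel(self, record: AlertRecord, t_now: float) -> AlertRecord:
        """User cancel; valid only while PENDING and before the deadline.
        Cancelling an already-cancelled record is a no-op."""
        if record.status is AlertStatus.CANCELLED:
            return record
        if record.status is not AlertStatus.PENDING:
            raise CancelAfterDeadlineError(
                f"alert {record.id} already {record.status.value}"
            )
        if t_now >= record.t_deadline:
            raise CancelAfterDeadlineError(
                f"cancel at t={t_now:g} after deadline {record.t_deadline:g}: "
                "escalation already fired"
            )
        record.status = AlertStatus.CANCELLED
        return record

    def tick(self, current_state: BehaviorState, t_now: float) -> list[NotificationAction]:
        """Advance the timers: every PENDING record past its deadline either
        escalates (wearer still FALLING/LYING) or auto-resolves as a false
        alarm."""
        emitted: list[NotificationAction] = []
        for record in self.records:
            if record.status is not AlertStatus.PENDING or t_now < record.t_deadline:
                continue
            if current_state in (BehaviorState.FALLING, BehaviorState.LYING):
                record.status = AlertStatus.CONFIRMED
                action = NotificationAction(
                    t=t_now, alert_id=record.id, stage="escalation",
                    payload={"state": current_state.value},
                )
                self._emit(action)
                emitted.append(action)
            else:
                record.status = AlertStatus.CANCELLED
        return emitted

    def action_log_jsonl(self) -> str:
        """All delivered actions (when a RecordingNotifier is attached) as
        JSON lines."""
        if isinstance(self.notifier, RecordingNotifier):
            return "\n".join(a.to_json() for a in self.notifier.actions)
        return "\n".join(a.to_json() for a in self.queued_actions)
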