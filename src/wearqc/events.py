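"""Event-log records: prompted/answered questionnaires, headaches, medication.

An event distinguishes *entry time* (when the participant logged it) from
*event time* (when it happened); the gap between the two is what the
sanity-check rules in :mod:`wearqc.compliance` police.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .timebase import ValidationError

__all__ = ["EventEntry", "EventLog", "EVENT_KINDS"]

EVENT_KINDS = frozenset(
    {
        "questionnaire_prompted",
        "questionnaire_answered",
        "headache",
        "medication",
        "timeline_prompted",
        "timeline_reviewed",
    }
)


@dataclass
class EventEntry:
    entry_time: float
    event_time_start: float
    kind: str
    event_time_end: float | None = None
    payload: str = ""

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.event_time_end is not None and self.event_time_end < self.event_time_start:
            raise ValidationError("event_time_end before event_time_start")


@dataclass
class EventLog:
    entries: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def of_kind(self, *kinds: str) -> list:
        return [e for e in self.entries if e.kind in kinds]
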