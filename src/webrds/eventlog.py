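"""Time-ordered survey event log and its JSONL serialization.

The log is the engine's unit of exchange: the recruitment simulator and
the deterministic funnel fixture both emit one, and the funnel replay,
fraud audit, and analytics tabulations all consume one.  On disk a log
is JSON Lines with a versioned header line followed by one event per
line, so it diffs and greps cleanly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

SCHEMA_NAME = "webrds-eventlog"
SCHEMA_VERSION = 1

EVENT_KINDS = frozenset(
    {
        "coupon_issued",
        "portal_entry",
        "otp_verified",
        "screened",
        "consented",
        "interview_started",
        "interview_completed",
        "coupons_sent",
        "payment_queued",
        "payment_paid",
        "fraud_flagged",
        "phone_rental_report",
    }
)


class EventLogError(ValueError):
    """Malformed event log (bad schema header or unparsable line)."""


@dataclass(frozen=True, slots=True)
class Event:
    t: int
    kind: str
    payload: dict[str, Any]

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise EventLogError(f"unknown event kind: {self.kind!r}")


@dataclass
class SurveyEventLog:
    """Ordered sequence of survey events plus run metadata (e.g. the seed)."""

    events: list[Event] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    def append(self, t: int, kind: str, **payload: Any) -> None:
        self.events.append(Event(int(t), kind, payload))

    def sort(self) -> None:
        """Stable sort by timestamp; ties keep emission order."""
        self.events.sort(key=lambda e: e.t)

    def of_kind(self, kind: str) -> Iterator[Event]:
        return (e for e in self.events if e.kind == kind)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyEventLog):
            return NotImplemented
        return self.events == other.events and self.meta == other.meta

    def check_monotone(self) -> None:
        for prev, cur in zip(self.events, self.events[1:]):
            if cur.t < prev.t:
                raise EventLogError("event timestamps are not nondecreasing")


def write_event_log(log: SurveyEventLog, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        header = {"schema": SCHEMA_NAME, "version": SCHEMA_VERSION, **log.meta}
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for e in log.events:
            fh.write(
                json.dumps({"t": e.t, "kind": e.kind, "payload": e.payload}) + "\n"
            )


def read_event_log(path: str) -> SurveyEventLog:
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise EventLogError("empty file: missing schema header")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise EventLogError(f"line 1: malformed header: {exc}") from exc
    if header.get("schema") != SCHEMA_NAME or header.get("version") != SCHEMA_VERSION:
        raise EventLogError(
            f"schema mismatch: expected {SCHEMA_NAME} v{SCHEMA_VERSION}, "
            f"got {header.get('schema')!r} v{header.get('version')!r}"
        )
    meta = {k: v for k, v in header.items() if k not in ("schema", "version")}
    log = SurveyEventLog(meta=meta)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            log.events.append(Event(int(obj["t"]), obj["kind"], obj["payload"]))
        except (KeyError, TypeError, ValueError, EventLogError) as exc:
            raise EventLogError(f"line {lineno}: {exc}") from exc
    return log


def events_from(records: Iterable[tuple[int, str, dict]]) -> SurveyEventLog:
    log = SurveyEventLog()
    for t, kind, payload in records:
        log.append(t, kind, **payload)
    return log
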