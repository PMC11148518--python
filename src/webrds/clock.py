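"""Single reference clock for the survey engine.

All timestamps are integer seconds since survey start.  Using one
monotone counter instead of wall-clock datetimes avoids time-zone
ambiguity in the scheduled payment ticks (the daily 02:00 referral
run) and makes simulated runs byte-reproducible.  A fixed epoch is
used only when serializing to ISO-8601 for CSV exports.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

MINUTE = 60
HOUR = 3600
DAY = 86400

#: Wall-clock anchor for t=0, used only for ISO-8601 serialization.
SURVEY_EPOCH = datetime(2022, 2, 1, 0, 0, 0, tzinfo=timezone.utc)


def to_iso(t: int | float | None) -> str:
    """Render a survey timestamp as an ISO-8601 UTC string ('' for None)."""
    if t is None:
        return ""
    return (SURVEY_EPOCH + timedelta(seconds=float(t))).strftime("%Y-%m-%dT%H:%M:%SZ")


def from_iso(s: str) -> int | None:
    """Parse an ISO-8601 UTC string back to seconds since survey start."""
    if not s:
        return None
    dt = datetime.strptime(s, "%Y-%m-%dT%H:%M:%SZ").replace(tzinfo=timezone.utc)
    return int((dt - SURVEY_EPOCH).total_seconds())
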