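"""Event-log container and CSV round-trip for operant sessions.

An :class:`EventLog` is the complete timestamped record of a single
subject-session: every nose-poke, infusion, cue, shock and phase
transition. Times are seconds from session start, quantized to
milliseconds so the CSV serialization round-trips bit-exactly.

Tie-breaking at equal timestamps follows a fixed event-type precedence
(phase transitions and time-out closure first, then pokes, then shock /
infusion / cue events, then time-out opening, session_end always last).
The time-out interval is half-open ``[timeout_start, timeout_end)``, so
the ``timeout_end`` marker sorts *before* a coincident poke: a poke
landing exactly at the end of a time-out is eligible for reinforcement
and a single forward scan of the log classifies it correctly.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .exceptions import LogParseError, ProtocolError

# Event types --------------------------------------------------------------

ACTIVE_POKE = "active_poke"
INACTIVE_POKE = "inactive_poke"
PRIMING_INFUSION = "priming_infusion"
INFUSION = "infusion"
CUE_ON = "cue_on"
CUE_OFF = "cue_off"
HOUSE_LIGHT_ON = "house_light_on"
HOUSE_LIGHT_OFF = "house_light_off"
TIMEOUT_START = "timeout_start"
TIMEOUT_END = "timeout_end"
SHOCK = "shock"
DRUGFREE_START = "drugfree_start"
DRUGFREE_END = "drugfree_end"
CUE_PHASE_START = "cue_phase_start"
SESSION_END = "session_end"

EVENT_TYPES = frozenset({
    ACTIVE_POKE, INACTIVE_POKE, PRIMING_INFUSION, INFUSION, CUE_ON, CUE_OFF,
    HOUSE_LIGHT_ON, HOUSE_LIGHT_OFF, TIMEOUT_START, TIMEOUT_END, SHOCK,
    DRUGFREE_START, DRUGFREE_END, CUE_PHASE_START, SESSION_END,
})

SESSION_KINDS = ("FR", "PR", "SHOCK", "EXTINCTION", "REINSTATEMENT")

#: Sort precedence for events sharing a timestamp.
PRECEDENCE: dict[str, int] = {
    HOUSE_LIGHT_ON: 0,
    HOUSE_LIGHT_OFF: 0,
    DRUGFREE_START: 0,
    DRUGFREE_END: 0,
    CUE_PHASE_START: 0,
    TIMEOUT_END: 1,       # closes the half-open time-out before coincident pokes
    PRIMING_INFUSION: 2,
    ACTIVE_POKE: 3,
    INACTIVE_POKE: 3,
    SHOCK: 4,
    INFUSION: 5,
    CUE_ON: 6,
    CUE_OFF: 7,
    TIMEOUT_START: 8,
    SESSION_END: 9,
}


def quantize(t: float) -> float:
    """Quantize a session time to milliseconds (the serialized resolution)."""
    return round(float(t), 3)


@dataclass
class Event:
    t: float
    event_type: str
    meta: dict[str, str] = field(default_factory=dict)

    def sort_key(self) -> tuple[float, int]:
        return (self.t, PRECEDENCE[self.event_type])


@dataclass
class EventLog:
    subject_id: str
    session_id: str
    session_kind: str
    events: list[Event] = field(default_factory=list)

    def sort(self) -> None:
        """Stable-sort events by (t, type precedence)."""
        self.events.sort(key=Event.sort_key)

    def count(self, event_type: str) -> int:
        return sum(1 for e in self.events if e.event_type == event_type)

    @property
    def end_time(self) -> float:
        return self.events[-1].t

    @property
    def end_meta(self) -> dict[str, str]:
        return self.events[-1].meta

    def validate(self) -> None:
        """Check structural invariants; raise ProtocolError on violation."""
        if self.session_kind not in SESSION_KINDS:
            raise ProtocolError(f"unknown session kind {self.session_kind!r}")
        if not self.events:
            raise ProtocolError("empty event log")
        keys = [e.sort_key() for e in self.events]
        if keys != sorted(keys):
            raise ProtocolError("events are not sorted by (t, precedence)")
        ends = [i for i, e in enumerate(self.events)
                if e.event_type == SESSION_END]
        if ends != [len(self.events) - 1]:
            raise ProtocolError("exactly one session_end required, last in log")
        for e in self.events:
            if e.event_type not in EVENT_TYPES:
                raise ProtocolError(f"unknown event type {e.event_type!r}")
            if e.t < 0:
                raise ProtocolError(f"negative timestamp {e.t}")


# CSV serialization --------------------------------------------------------

CSV_HEADER = ["subject_id", "session_id", "session_kind", "t_s",
              "event_type", "meta"]

_META_FORBIDDEN = set(";=,\n\r")


def _encode_meta(meta: dict[str, str]) -> str:
    parts = []
    for k, v in meta.items():
        v = str(v)
        if _META_FORBIDDEN & (set(k) | set(v)):
            raise ProtocolError(f"meta entry {k!r}={v!r} contains ';', '=' or ','")
        parts.append(f"{k}={v}")
    return ";".join(parts)


def _decode_meta(s: str, where: str) -> dict[str, str]:
    if not s:
        return {}
    meta = {}
    for part in s.split(";"):
        if "=" not in part:
            raise LogParseError(f"{where}: malformed meta field {part!r}")
        k, _, v = part.partition("=")
        meta[k] = v
    return meta


def event_log_to_csv(log: EventLog) -> str:
    """Serialize one subject-session to CSV text (LF endings, 3-decimal t)."""
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(CSV_HEADER)
    for e in log.events:
        w.writerow([log.subject_id, log.session_id, log.session_kind,
                    f"{e.t:.3f}", e.event_type, _encode_meta(e.meta)])
    return buf.getvalue()


def write_event_log(log: EventLog, path: str | Path) -> None:
    Path(path).write_text(event_log_to_csv(log), encoding="utf-8", newline="")


def event_log_from_csv(text: str, source: str = "<string>") -> EventLog:
    rows = list(csv.reader(io.StringIO(text)))
    if not rows or rows[0] != CSV_HEADER:
        raise LogParseError(f"{source}: missing or invalid header row")
    log: EventLog | None = None
    for i, row in enumerate(rows[1:], start=2):
        where = f"{source}:row {i}"
        if len(row) != len(CSV_HEADER):
            raise LogParseError(f"{where}: expected {len(CSV_HEADER)} fields, "
                                f"got {len(row)}")
        subj, sess, kind, t_s, etype, meta_s = row
        if log is None:
            log = EventLog(subject_id=subj, session_id=sess, session_kind=kind)
        elif (subj, sess, kind) != (log.subject_id, log.session_id,
                                    log.session_kind):
            raise LogParseError(f"{where}: mixed subject/session identifiers")
        if etype not in EVENT_TYPES:
            raise LogParseError(f"{where}: unknown event type {etype!r}")
        try:
            t = float(t_s)
        except ValueError:
            raise LogParseError(f"{where}: bad timestamp {t_s!r}") from None
        log.events.append(Event(t, etype, _decode_meta(meta_s, where)))
    if log is None:
        raise LogParseError(f"{source}: no event rows")
    return log


def read_event_log(path: str | Path) -> EventLog:
    return event_log_from_csv(Path(path).read_text(encoding="utf-8"), str(path))
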