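"""Clinical event-log data model, readers/writers, and the cleaning pipeline.

An event log records timestamped activities, each attributed to a case (one
patient's pathway through the department) and a resource (the staff member,
with their professional role). Logs exported from an EMR are messy: timestamps
can be missing or obviously wrong, the same action can be logged twice, labels
vary ("QA" vs "QA Check"), and some cases never complete the pathway. The
:func:`clean_log` pipeline applies, in a fixed order: bad-timestamp removal,
duplicate consolidation, label normalization, and completeness filtering, and
reports exactly what it did so event totals always reconcile.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from lxml import etree

__all__ = [
    "ROLES",
    "CANONICAL_ACTIVITIES",
    "DEFAULT_SYNONYMS",
    "Event",
    "Trace",
    "EventLog",
    "CleaningConfig",
    "CleaningReport",
    "Violation",
    "ConfigurationError",
    "EmptyInputError",
    "read_csv_log",
    "write_csv_log",
    "read_xes_log",
    "clean_log",
    "validate_log",
]

#: Professional roles recognized in a radiotherapy care pathway.
ROLES = frozenset({"dosimetrist", "physicist", "physician", "therapist", "other"})

#: The canonical four-stage care pathway, in protocol order.
CANONICAL_ACTIVITIES = ("CT-Sim", "Planning", "QA Check", "Treatment")

#: Default raw-label -> canonical-label normalization table.
DEFAULT_SYNONYMS = {
    "CT Sim": "CT-Sim",
    "CTSim": "CT-Sim",
    "Plan": "Planning",
    "QA": "QA Check",
    "Tx": "Treatment",
}

CSV_COLUMNS = ("case_id", "activity", "resource", "role", "timestamp")


class ConfigurationError(ValueError):
    """A reader/cleaner configuration is invalid or incomplete."""


class EmptyInputError(ValueError):
    """An input contained no usable rows/traces."""


def _parse_timestamp(raw: str) -> datetime:
    # Timezone-naive local clinic time; sub-second precision truncated.
    ts = datetime.fromisoformat(str(raw).strip())
    if ts.tzinfo is not None:
        ts = ts.replace(tzinfo=None)
    return ts.replace(microsecond=0)


def _coerce_role(raw: str | None) -> str:
    role = (raw or "").strip().lower()
    return role if role in ROLES else "other"


@dataclass(frozen=True)
class Event:
    """One logged action: who did what, for which case, when."""

    case_id: str
    activity: str
    resource: str
    role: str
    timestamp: datetime

    def as_row(self) -> dict:
        return {
            "case_id": self.case_id,
            "activity": self.activity,
            "resource": self.resource,
            "role": self.role,
            "timestamp": self.timestamp.isoformat(timespec="seconds"),
        }


@dataclass
class Trace:
    """The ordered event sequence for one case.

    Events are kept sorted by timestamp; ties preserve input order (the sort
    is stable, so equal-timestamp events are never reordered).
    """

    case_id: str
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: e.timestamp)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Event]:
        return iter(self.events)

    @property
    def activities(self) -> list[str]:
        return [e.activity for e in self.events]


@dataclass
class EventLog:
    """A collection of traces plus the log-level context cleaning needs.

    ``collection_end`` is the declared end of data collection: any timestamp
    after it is "obviously incorrect". ``required_activities`` is the ordered
    canonical pathway a complete case must contain. ``unparseable`` holds raw
    input rows whose timestamp could not be parsed; they are retained here so
    nothing is silently dropped, and counted as bad-timestamp removals by
    :func:`clean_log`.
    """

    traces: list[Trace] = field(default_factory=list)
    collection_end: date | None = None
    required_activities: tuple[str, ...] = CANONICAL_ACTIVITIES
    unparseable: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.traces)

    @property
    def case_ids(self) -> list[str]:
        return [t.case_id for t in self.traces]

    @property
    def n_events(self) -> int:
        return sum(len(t) for t in self.traces)

    def trace(self, case_id: str) -> Trace:
        for t in self.traces:
            if t.case_id == case_id:
                return t
        raise KeyError(case_id)

    def events(self) -> Iterator[Event]:
        for t in self.traces:
            yield from t.events


@dataclass
class CleaningReport:
    """Accounting of every action :func:`clean_log` took."""

    n_input_events: int = 0
    n_removed_bad_timestamp: int = 0
    n_flagged_out_of_sequence: int = 0
    n_duplicates_consolidated: int = 0
    n_cases_discarded_incomplete: int = 0
    n_events_discarded_incomplete: int = 0
    n_output_events: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class CleaningConfig:
    """Parameters of the cleaning pipeline.

    collection_end
        Declared end of data collection; later timestamps are removed.
    required_activities
        Ordered canonical pathway; cases missing any stage are discarded.
    synonyms
        Raw-label -> canonical-label table applied before the completeness
        filter.
    earliest_plausible
        Timestamps before this date are treated as obviously incorrect.
    drop_out_of_sequence
        If True, events whose pathway stage regresses relative to an earlier
        event are removed rather than merely flagged. Default off: flagging is
        lossless and correction rules are site-specific.
    """

    collection_end: date
    required_activities: Sequence[str] = CANONICAL_ACTIVITIES
    synonyms: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SYNONYMS))
    earliest_plausible: date = date(2000, 1, 1)
    drop_out_of_sequence: bool = False


@dataclass(frozen=True)
class Violation:
    case_id: str | None
    kind: str
    detail: str


# ---------------------------------------------------------------------------
# readers / writers


def _build_log(events: Iterable[Event], **kwargs) -> EventLog:
    by_case: dict[str, list[Event]] = {}
    for ev in events:
        by_case.setdefault(ev.case_id, []).append(ev)
    traces = [Trace(cid, evs) for cid, evs in by_case.items()]
    return EventLog(traces=traces, **kwargs)


def read_csv_log(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    collection_end: date | None = None,
    required_activities: Sequence[str] = CANONICAL_ACTIVITIES,
) -> EventLog:
    """Read an event log from CSV.

    ``dialect`` maps canonical column names (``case_id``, ``activity``,
    ``resource``, ``role``, ``timestamp``) to the file's actual header names;
    unmapped names are used as-is. Rows whose timestamp does not parse are
    collected on ``log.unparseable`` rather than silently dropped. Input row
    order is the tie-break order for equal timestamps.
    """
    path = Path(path)
    colmap = {c: (dialect or {}).get(c, c) for c in CSV_COLUMNS}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for canon in ("case_id", "activity", "timestamp"):
            if colmap[canon] not in header:
                raise ConfigurationError(
                    f"mapped column {colmap[canon]!r} (for {canon!r}) not in header {header}"
                )
        events: list[Event] = []
        unparseable: list[dict] = []
        for row in reader:
            raw_ts = row.get(colmap["timestamp"], "")
            try:
                ts = _parse_timestamp(raw_ts)
            except (ValueError, TypeError):
                unparseable.append(dict(row))
                continue
            events.append(
                Event(
                    case_id=str(row[colmap["case_id"]]).strip(),
                    activity=str(row[colmap["activity"]]).strip(),
                    resource=str(row.get(colmap["resource"]) or "unknown").strip(),
                    role=_coerce_role(row.get(colmap["role"])),
                    timestamp=ts,
                )
            )
    if not events and not unparseable:
        raise EmptyInputError(f"no parseable event rows in {path}")
    return _build_log(
        events,
        collection_end=collection_end,
        required_activities=tuple(required_activities),
        unparseable=unparseable,
    )


def write_csv_log(log: EventLog, path: str | Path) -> Path:
    """Write a log to CSV (RFC-4180 quoting, canonical columns).

    Round-trips through :func:`read_csv_log` event-for-event.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
        writer.writeheader()
        for ev in log.events():
            writer.writerow(ev.as_row())
    return path


_XES_NS = "{http://www.xes-standard.org/}"


def _xes_attr(elem, key: str) -> str | None:
    for child in elem:
        if child.get("key") == key:
            return child.get("value")
    return None


def read_xes_log(
    path: str | Path,
    collection_end: date | None = None,
    required_activities: Sequence[str] = CANONICAL_ACTIVITIES,
) -> EventLog:
    """Read an event log in the XES process-mining interchange format.

    ``concept:name`` on traces maps to case_id and on events to activity;
    ``time:timestamp`` to timestamp; ``org:resource``/``org:role`` (when
    present) to resource/role, else ``resource="unknown"``, ``role="other"``.
    Traces with no events are retained (flagged later by validate_log).
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XES ({path}): {exc}") from exc
    root = tree.getroot()
    traces: list[Trace] = []
    for tr in root.iter():
        if etree.QName(tr).localname != "trace":
            continue
        case_id = _xes_attr(tr, "concept:name") or f"case-{len(traces)}"
        events: list[Event] = []
        for ev in tr:
            if etree.QName(ev).localname != "event":
                continue
            activity = _xes_attr(ev, "concept:name") or ""
            raw_ts = _xes_attr(ev, "time:timestamp")
            ts = _parse_timestamp(raw_ts) if raw_ts else None
            if ts is None:
                continue
            events.append(
                Event(
                    case_id=case_id,
                    activity=activity.strip(),
                    resource=(_xes_attr(ev, "org:resource") or "unknown").strip(),
                    role=_coerce_role(_xes_attr(ev, "org:role")),
                    timestamp=ts,
                )
            )
        traces.append(Trace(case_id, events))
    return EventLog(
        traces=traces,
        collection_end=collection_end,
        required_activities=tuple(required_activities),
    )


# ---------------------------------------------------------------------------
# cleaning & validation


def _stage_index(required: Sequence[str]) -> dict[str, int]:
    return {a: i for i, a in enumerate(required)}


def clean_log(log: EventLog, config: CleaningConfig) -> tuple[EventLog, CleaningReport]:
    """Apply the cleaning pipeline and account for every event.

    Fixed order: (1) remove events with unparseable timestamps, timestamps
    after ``collection_end``, or before ``earliest_plausible``; (2) within each
    case, consolidate events identical in (timestamp, activity) to the first
    occurrence; (3) normalize activity labels through the synonym table;
    (4) discard cases missing any required activity. Idempotent: cleaning a
    cleaned log changes nothing and reports all-zero counts.
    """
    if not config.required_activities:
        raise ConfigurationError("required_activities must be non-empty")
    end = datetime.combine(config.collection_end, datetime.max.time()).replace(
        microsecond=0
    )
    earliest = datetime.combine(config.earliest_plausible, datetime.min.time())
    report = CleaningReport(n_input_events=log.n_events + len(log.unparseable))
    report.n_removed_bad_timestamp = len(log.unparseable)

    stage = _stage_index(config.required_activities)
    cleaned_traces: list[Trace] = []
    for tr in log.traces:
        # (1) bad timestamps
        kept = []
        for ev in tr.events:
            if ev.timestamp > end or ev.timestamp < earliest:
                report.n_removed_bad_timestamp += 1
            else:
                kept.append(ev)
        # (2) duplicate consolidation, first occurrence wins
        seen: set[tuple[datetime, str]] = set()
        deduped = []
        for ev in kept:
            key = (ev.timestamp, ev.activity)
            if key in seen:
                report.n_duplicates_consolidated += 1
            else:
                seen.add(key)
                deduped.append(ev)
        # (3) label normalization
        normalized = [
            replace(ev, activity=config.synonyms.get(ev.activity, ev.activity))
            for ev in deduped
        ]
        # out-of-sequence flagging (stage regression among required activities)
        flagged: list[Event] = []
        running_max = -1
        for ev in normalized:
            idx = stage.get(ev.activity)
            if idx is not None:
                if idx < running_max:
                    report.n_flagged_out_of_sequence += 1
                    if config.drop_out_of_sequence:
                        continue
                running_max = max(running_max, idx)
            flagged.append(ev)
        cleaned_traces.append(Trace(tr.case_id, flagged))

    # (4) completeness filter
    required = set(config.required_activities)
    final_traces = []
    for tr in cleaned_traces:
        if required.issubset(set(tr.activities)):
            final_traces.append(tr)
        else:
            report.n_cases_discarded_incomplete += 1
            report.n_events_discarded_incomplete += len(tr)
    report.n_output_events = sum(len(t) for t in final_traces)

    cleaned = EventLog(
        traces=final_traces,
        collection_end=config.collection_end,
        required_activities=tuple(config.required_activities),
        unparseable=[],
    )
    return cleaned, report


def validate_log(log: EventLog) -> list[Violation]:
    """Re-check a log's structural invariants; never raises on content.

    Detects: duplicate case ids, events not sorted by timestamp, events whose
    case_id disagrees with their trace, empty traces, missing required
    activities, and pathway-stage regressions (e.g. Treatment timestamped
    before CT-Sim).
    """
    violations: list[Violation] = []
    seen_ids: set[str] = set()
    stage = _stage_index(log.required_activities)
    for tr in log.traces:
        if tr.case_id in seen_ids:
            violations.append(
                Violation(tr.case_id, "duplicate_case_id", "case id occurs more than once")
            )
        seen_ids.add(tr.case_id)
        if not tr.events:
            violations.append(Violation(tr.case_id, "empty_trace", "trace has no events"))
            continue
        ts = [e.timestamp for e in tr.events]
        if any(a > b for a, b in zip(ts, ts[1:])):
            violations.append(
                Violation(tr.case_id, "unsorted_events", "events not in timestamp order")
            )
        for ev in tr.events:
            if ev.case_id != tr.case_id:
                violations.append(
                    Violation(tr.case_id, "case_id_mismatch", f"event carries {ev.case_id!r}")
                )
        missing = set(log.required_activities) - set(tr.activities)
        if missing:
            violations.append(
                Violation(
                    tr.case_id,
                    "missing_required_activity",
                    "missing: " + ", ".join(sorted(missing)),
                )
            )
        running_max = -1
        n_regress = 0
        for ev in tr.events:
            idx = stage.get(ev.activity)
            if idx is None:
                continue
            if idx < running_max:
                n_regress += 1
            running_max = max(running_max, idx)
        if n_regress:
            violations.append(
                Violation(
                    tr.case_id,
                    "out_of_sequence",
                    f"{n_regress} event(s) regress the pathway stage order",
                )
            )
    return violations
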