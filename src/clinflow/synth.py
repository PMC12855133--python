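"""Synthetic generators for every input the pipeline consumes.

Real clinical event logs are rarely shareable, so the package ships
generators that emulate their *structure*: four-stage care-pathway traces
(CT-Sim -> Planning -> QA Check -> Treatment) with controlled non-conformant
variants and planted data defects, calendar drift in which role performs the
work, and growing team/artifact/information networks. The generators emulate
structure, not any particular department's distribution.

All generators are deterministic given their seed. Per-case random streams
are derived from (seed, case index), so raising the deviation probability
turns additional cases non-conformant without re-randomizing the rest — the
injected deviation fraction is always recoverable from the emitted log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, timedelta

import numpy as np

from .entropy import NetworkSnapshot
from .eventlog import CANONICAL_ACTIVITIES, ConfigurationError, Event, EventLog, Trace

__all__ = [
    "DEVIATION_KINDS",
    "LogGenConfig",
    "NetGenConfig",
    "DEMO_DRIFT_SCHEDULE",
    "demo_network_config",
    "generate_log",
    "generate_network_series",
    "generate_role_drift_log",
    "planted_defect_log",
    "write_network_csv",
]

DEVIATION_KINDS = ("skip", "swap", "repeat", "replan_loop")

#: Which role naturally performs each pathway stage (used when no explicit
#: role schedule is supplied).
STAGE_ROLE = {
    "CT-Sim": "therapist",
    "Planning": "dosimetrist",
    "QA Check": "physicist",
    "Treatment": "therapist",
}

#: Autumn drift demonstration schedule: the dosimetrist share falls from 51%
#: to 43% while the physicist share rises to 23%, the physician share holds a
#: steady quarter, and the therapist share absorbs the remainder.
DEMO_DRIFT_SCHEDULE = {
    "2024-09": {"dosimetrist": 0.51, "physicist": 0.17, "physician": 0.25, "therapist": 0.07},
    "2024-10": {"dosimetrist": 0.48, "physicist": 0.19, "physician": 0.26, "therapist": 0.07},
    "2024-11": {"dosimetrist": 0.46, "physicist": 0.21, "physician": 0.24, "therapist": 0.09},
    "2024-12": {"dosimetrist": 0.43, "physicist": 0.23, "physician": 0.25, "therapist": 0.09},
}


@dataclass
class LogGenConfig:
    """Care-pathway log generator settings.

    ``deviation_rate`` is the per-case probability of emitting a
    non-conformant variant, drawn from ``deviation_mix`` over: skip (drop one
    interior stage), swap (transpose an adjacent stage pair), repeat (log one
    stage twice at distinct times), replan_loop (a second Planning -> QA
    Check pass before Treatment). ``defect_rates`` are per-case probabilities
    of planting a data defect the cleaning pipeline must handle: an extra
    future-dated event, an exact duplicate event, or a dropped Treatment
    making the case incomplete. Inter-stage gaps are log-normal with a median
    of one day.
    """

    n_cases: int = 40
    deviation_rate: float = 0.0
    deviation_mix: dict = field(
        default_factory=lambda: {k: 0.25 for k in DEVIATION_KINDS}
    )
    role_schedule: dict | None = None  # "YYYY-MM" -> {role: share}
    defect_rates: dict = field(
        default_factory=lambda: {"future_timestamp": 0.0, "duplicate": 0.0, "incomplete_case": 0.0}
    )
    start_date: date = date(2024, 9, 1)
    window_length_days: int = 90
    collection_end: date | None = None
    gap_sigma: float = 0.5  # sigma of ln(gap in days); median gap 1 day
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.deviation_rate <= 1.0:
            raise ConfigurationError("deviation_rate must be in [0, 1]")
        for k, v in self.defect_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"defect rate {k} must be in [0, 1]")
        weights = np.array([self.deviation_mix.get(k, 0.0) for k in DEVIATION_KINDS])
        if (weights < 0).any() or not np.isclose(weights.sum(), 1.0):
            raise ConfigurationError("deviation_mix weights must be >= 0 and sum to 1")
        if self.role_schedule is not None:
            for month, shares in self.role_schedule.items():
                if abs(sum(shares.values()) - 1.0) > 1e-9:
                    raise ConfigurationError(f"role shares for {month} must sum to 1")
        if self.collection_end is None:
            self.collection_end = self.start_date + timedelta(
                days=self.window_length_days + 30
            )


def _case_rng(seed: int, case_idx: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, case_idx, stream])


def _deviate(activities: list[str], rng: np.random.Generator) -> tuple[list[str], str]:
    kinds = list(DEVIATION_KINDS)
    kind = kinds[int(rng.integers(len(kinds)))]
    return _apply_deviation(activities, kind, rng), kind


def _apply_deviation(
    activities: list[str], kind: str, rng: np.random.Generator
) -> list[str]:
    acts = list(activities)
    if kind == "skip":
        interior = [i for i in range(1, len(acts) - 1)]
        acts.pop(int(rng.choice(interior)))
    elif kind == "swap":
        i = int(rng.integers(len(acts) - 1))
        acts[i], acts[i + 1] = acts[i + 1], acts[i]
    elif kind == "repeat":
        i = int(rng.integers(len(acts)))
        acts.insert(i + 1, acts[i])
    elif kind == "replan_loop":
        # second Planning -> QA Check pass before the final stage
        acts = acts[:-1] + ["Planning", "QA Check"] + acts[-1:]
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown deviation kind {kind!r}")
    return acts


def _pick_role(
    activity: str, ts: datetime, schedule: dict | None, rng: np.random.Generator
) -> str:
    if schedule is None:
        return STAGE_ROLE.get(activity, "other")
    month = f"{ts.year:04d}-{ts.month:02d}"
    shares = schedule.get(month)
    if shares is None:
        # outside the scheduled horizon fall back to the nearest window
        key = min(schedule, key=lambda m: abs((int(m[:4]) * 12 + int(m[5:])) - (ts.year * 12 + ts.month)))
        shares = schedule[key]
    roles = sorted(shares)
    probs = np.array([shares[r] for r in roles])
    return roles[int(rng.choice(len(roles), p=probs / probs.sum()))]


def generate_log(config: LogGenConfig) -> EventLog:
    """Generate a care-pathway event log with controlled deviations/defects.

    With probability ``1 - deviation_rate`` a case is the exact four-stage
    pathway with strictly increasing timestamps; otherwise one deviation from
    ``deviation_mix`` is applied. Defects are injected after pathway
    construction. Identical configs (including seed) give identical logs.
    """
    traces: list[Trace] = []
    spacing_h = config.window_length_days * 24.0 / max(config.n_cases, 1)
    for i in range(config.n_cases):
        rng_dev = _case_rng(config.seed, i, 1)
        rng_time = _case_rng(config.seed, i, 2)
        rng_defect = _case_rng(config.seed, i, 3)
        rng_role = _case_rng(config.seed, i, 4)

        activities = list(CANONICAL_ACTIVITIES)
        if rng_dev.random() < config.deviation_rate:
            weights = np.array([config.deviation_mix.get(k, 0.0) for k in DEVIATION_KINDS])
            kind = DEVIATION_KINDS[int(rng_dev.choice(len(DEVIATION_KINDS), p=weights))]
            activities = _apply_deviation(activities, kind, rng_dev)

        start = datetime.combine(config.start_date, datetime.min.time()) + timedelta(
            hours=i * spacing_h + float(rng_time.uniform(8, 17))
        )
        ts = start
        events: list[Event] = []
        case_id = f"case-{i:04d}"
        for act in activities:
            events.append(
                Event(
                    case_id=case_id,
                    activity=act,
                    resource=f"staff-{rng_role.integers(1, 9)}",
                    role=_pick_role(act, ts, config.role_schedule, rng_role),
                    timestamp=ts.replace(microsecond=0),
                )
            )
            gap_days = float(np.exp(rng_time.normal(0.0, config.gap_sigma)))
            ts = ts + timedelta(days=gap_days)

        # planted defects, applied after the pathway is built
        if rng_defect.random() < config.defect_rates.get("future_timestamp", 0.0):
            future = datetime.combine(config.collection_end, datetime.min.time()) + timedelta(
                days=400, hours=12
            )
            src = events[int(rng_defect.integers(len(events)))]
            events.append(
                Event(case_id, src.activity, src.resource, src.role, future)
            )
        if rng_defect.random() < config.defect_rates.get("duplicate", 0.0):
            # exact duplicate: same timestamp and activity
            events.append(events[int(rng_defect.integers(len(events)))])
        if rng_defect.random() < config.defect_rates.get("incomplete_case", 0.0):
            keep = [e for e in events if e.activity != "Treatment"]
            events = keep if keep else events

        traces.append(Trace(case_id, events))
    return EventLog(
        traces=traces,
        collection_end=config.collection_end,
        required_activities=CANONICAL_ACTIVITIES,
    )


@dataclass
class NetGenConfig:
    """Growing department-network generator settings.

    Starts from a fully interconnected team of ``n_team`` people; each year
    adds the given numbers of artifact and information nodes, each attaching
    links to existing nodes either uniformly at random or preferentially by
    degree (with +1 smoothing so isolated nodes stay reachable). With
    ``heterogeneous_edges`` off every new node brings exactly
    ``edges_per_new_node`` links; with it on, each new node draws its link
    count uniformly from 1..``edges_per_new_node`` — some additions (a new
    accelerator) touch nearly everyone, others (a minor protocol update)
    touch one person, which is what keeps the degree distribution spreading
    as the system grows.
    """

    n_team: int = 8
    artifacts_per_year: tuple = (2, 4, 8)
    info_per_year: tuple = (3, 6, 12)
    attach_rule: str = "preferential"
    edges_per_new_node: int = 2
    heterogeneous_edges: bool = False
    labels: tuple | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.artifacts_per_year) != len(self.info_per_year):
            raise ConfigurationError("artifact and information sequences must match in length")
        if any(n < 0 for n in self.artifacts_per_year + self.info_per_year):
            raise ConfigurationError("counts must be non-negative")
        if self.attach_rule not in ("uniform", "preferential"):
            raise ConfigurationError("attach_rule must be 'uniform' or 'preferential'")
        if self.labels is not None and len(self.labels) != len(self.artifacts_per_year):
            raise ConfigurationError("labels must match the number of years")


def demo_network_config(seed: int = 0) -> NetGenConfig:
    """The package's standard growth scenario: an eight-member team whose
    environment gains artifacts and information at an accelerating pace
    ((2, 6, 18) artifacts and (3, 9, 27) information items over three
    periods) with heterogeneous preferential attachment. Entropy rises
    period over period under this scenario."""
    return NetGenConfig(
        n_team=8,
        artifacts_per_year=(2, 6, 18),
        info_per_year=(3, 9, 27),
        attach_rule="preferential",
        edges_per_new_node=8,
        heterogeneous_edges=True,
        labels=("period-1", "period-2", "period-3"),
        seed=seed,
    )


def generate_network_series(config: NetGenConfig) -> list[NetworkSnapshot]:
    """Grow the department network and snapshot it after each year.

    Snapshots are nested: every node and edge of an earlier snapshot is
    present in all later ones.
    """
    import networkx as nx

    rng = np.random.default_rng(config.seed)
    g = nx.Graph()
    team = [f"team-{i}" for i in range(config.n_team)]
    for n in team:
        g.add_node(n, kind="team")
    for i, u in enumerate(team):
        for v in team[i + 1 :]:
            g.add_edge(u, v)

    def attach(new_node: str, kind: str) -> None:
        existing = sorted(n for n in g.nodes if n != new_node)
        g.add_node(new_node, kind=kind)
        if config.heterogeneous_edges:
            n_links = int(rng.integers(1, config.edges_per_new_node + 1))
        else:
            n_links = config.edges_per_new_node
        k = min(n_links, len(existing))
        if k == 0:
            return
        if config.attach_rule == "uniform":
            targets = rng.choice(len(existing), size=k, replace=False)
        else:
            weights = np.array([g.degree(n) + 1.0 for n in existing])
            targets = rng.choice(len(existing), size=k, replace=False, p=weights / weights.sum())
        for idx in targets:
            g.add_edge(new_node, existing[int(idx)])

    snapshots: list[NetworkSnapshot] = []
    n_art = n_info = 0
    for year, (na, ni) in enumerate(zip(config.artifacts_per_year, config.info_per_year)):
        for _ in range(na):
            attach(f"artifact-{n_art}", "artifact")
            n_art += 1
        for _ in range(ni):
            attach(f"info-{n_info}", "information")
            n_info += 1
        label = (
            str(config.labels[year]) if config.labels is not None else f"year-{year + 1}"
        )
        snapshots.append(NetworkSnapshot(label=label, graph=g.copy()))
    return snapshots


def generate_role_drift_log(
    shares_by_month: dict,
    n_events_per_month: int,
    seed: int = 0,
) -> EventLog:
    """Generate a log whose per-month role shares follow a given schedule.

    ``shares_by_month`` maps "YYYY-MM" to {role: share} (each month summing
    to 1). Events are grouped four-at-a-time into pathway-ordered cases with
    timestamps uniform within the month; each event's role is an independent
    draw from its month's shares, so the schedule is recoverable up to
    multinomial sampling error.
    """
    for month, shares in shares_by_month.items():
        if abs(sum(shares.values()) - 1.0) > 1e-9:
            raise ConfigurationError(f"role shares for {month} must sum to 1")
    rng = np.random.default_rng(seed)
    traces: list[Trace] = []
    case_no = 0
    for month in sorted(shares_by_month):
        year, mon = int(month[:4]), int(month[5:])
        month_start = datetime(year, mon, 1)
        next_month = datetime(year + (mon == 12), mon % 12 + 1, 1)
        span_s = (next_month - month_start).total_seconds()
        offsets = np.sort(rng.uniform(0, span_s - 1, size=n_events_per_month))
        shares = shares_by_month[month]
        roles = sorted(shares)
        probs = np.array([shares[r] for r in roles])
        drawn = rng.choice(len(roles), size=n_events_per_month, p=probs / probs.sum())
        events_buf: list[Event] = []
        for j in range(n_events_per_month):
            if j % 4 == 0:
                if events_buf:
                    traces.append(Trace(events_buf[0].case_id, events_buf))
                    events_buf = []
                case_no += 1
            case_id = f"case-{case_no:05d}"
            events_buf.append(
                Event(
                    case_id=case_id,
                    activity=CANONICAL_ACTIVITIES[j % 4],
                    resource=f"staff-{int(rng.integers(1, 9))}",
                    role=roles[int(drawn[j])],
                    timestamp=(month_start + timedelta(seconds=float(offsets[j]))).replace(
                        microsecond=0
                    ),
                )
            )
        if events_buf:
            traces.append(Trace(events_buf[0].case_id, events_buf))
    return EventLog(traces=traces, required_activities=CANONICAL_ACTIVITIES)


def planted_defect_log() -> tuple[EventLog, dict]:
    """Deterministic hand-built log with known defects, plus expected cleanup.

    Ten cases: nine complete four-stage pathways and one incomplete case
    (no QA Check, 4 events). Planted defects: three future-dated extra events
    (beyond the 2024-12-31 collection end), two exact duplicate events (same
    timestamp and activity), and one raw "QA" label needing normalization.
    45 events in; cleaning must remove 3, consolidate 2, discard 1 case
    (4 events), leaving 36.
    """
    base = datetime(2024, 9, 2, 9, 0, 0)
    traces = []
    for i in range(9):
        cid = f"case-{i:02d}"
        start = base + timedelta(days=7 * i)
        events = []
        for j, act in enumerate(CANONICAL_ACTIVITIES):
            raw = "QA" if (i == 5 and act == "QA Check") else act
            events.append(
                Event(cid, raw, f"staff-{j + 1}", STAGE_ROLE.get(act, "other"),
                      start + timedelta(days=j))
            )
        if i < 3:  # future-dated extras, removed by cleaning
            events.append(
                Event(cid, "Treatment", "staff-4", "therapist", datetime(2025, 6, 1, 12, 0, 0))
            )
        if i in (3, 4):  # exact duplicates of the Planning event
            events.append(events[1])
        traces.append(Trace(cid, events))
    cid = "case-09"
    start = base + timedelta(days=70)
    incomplete = [
        Event(cid, "CT-Sim", "staff-1", "therapist", start),
        Event(cid, "Planning", "staff-2", "dosimetrist", start + timedelta(days=1)),
        Event(cid, "Planning", "staff-2", "dosimetrist", start + timedelta(days=2)),
        Event(cid, "Treatment", "staff-4", "therapist", start + timedelta(days=3)),
    ]
    traces.append(Trace(cid, incomplete))
    log = EventLog(
        traces=traces,
        collection_end=date(2024, 12, 31),
        required_activities=CANONICAL_ACTIVITIES,
    )
    expected = {
        "n_input_events": 45,
        "n_removed_bad_timestamp": 3,
        "n_duplicates_consolidated": 2,
        "n_cases_discarded_incomplete": 1,
        "n_events_discarded_incomplete": 4,
        "n_output_events": 36,
    }
    return log, expected


def write_network_csv(net: NetworkSnapshot, path) -> None:
    """Write a snapshot as a source,target edge-list CSV."""
    from pathlib import Path

    lines = ["source,target"]
    for u, v in sorted(net.graph.edges()):
        lines.append(f"{u},{v}")
    Path(path).write_text("\n".join(lines) + "\n")
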