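"""Organizational mining: role-activity shares over calendar windows and
handover-of-work networks.

Self-organization in a department shows up as drift in who does what: the
fraction of logged events attributable to each professional role shifts from
month to month without any directive mandating it. ``role_activity_shares``
buckets events by the calendar window of their timestamp and reports each
role's share of the window's events ("activities" are counted as events; the
denominator is the window's total event count, stated in output metadata).
``handover_network`` counts, within each case, directed handovers from the
actor of one event to the actor of the next.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .eventlog import ROLES, EmptyInputError, EventLog

__all__ = [
    "RoleActivityMatrix",
    "DriftRecord",
    "HandoverNetwork",
    "role_activity_shares",
    "share_drift",
    "handover_network",
]


@dataclass
class RoleActivityMatrix:
    """Per-window role shares and the counts behind them.

    ``windows`` are ordered calendar labels ("2024-09" for months, "2024-W37"
    for ISO weeks). Roles with no events in a window carry an explicit share
    of 0. ``warnings`` records interior windows that contained no events and
    were omitted.
    """

    windows: list[str]
    roles: list[str]
    counts: dict[tuple[str, str], int]
    shares: dict[tuple[str, str], float]
    denominator: str = "events"
    warnings: list[str] = field(default_factory=list)

    def share_series(self, role: str) -> list[float]:
        return [self.shares[(w, role)] for w in self.windows]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "window": w,
                "role": r,
                "count": self.counts[(w, r)],
                "share": self.shares[(w, r)],
            }
            for w in self.windows
            for r in self.roles
        ]
        return pd.DataFrame(rows)


@dataclass
class DriftRecord:
    role: str
    first_share: float
    last_share: float
    change: float
    diff_signs: list[int]  # sign of each successive window-to-window change

    @property
    def monotone_increasing(self) -> bool:
        return all(s >= 0 for s in self.diff_signs)

    @property
    def monotone_decreasing(self) -> bool:
        return all(s <= 0 for s in self.diff_signs)


def role_activity_shares(log: EventLog, window: str = "month") -> RoleActivityMatrix:
    """Bucket events by calendar window and compute each role's event share."""
    if log.n_events == 0:
        raise EmptyInputError("log has no events")
    if window not in ("month", "week"):
        raise ValueError("window must be 'month' or 'week'")
    freq = "M" if window == "month" else "W"
    recs = [(ev.timestamp, ev.role) for ev in log.events()]
    df = pd.DataFrame(recs, columns=["timestamp", "role"])
    if window == "month":
        df["window"] = df["timestamp"].dt.to_period("M").astype(str)
    else:
        iso = df["timestamp"].dt.isocalendar()
        df["window"] = iso.year.astype(str) + "-W" + iso.week.astype(str).str.zfill(2)

    present = sorted(df["window"].unique())
    # enumerate the full calendar range to surface empty interior windows
    full = pd.period_range(
        df["timestamp"].min().to_period(freq), df["timestamp"].max().to_period(freq), freq=freq
    )
    if window == "month":
        expected = [str(p) for p in full]
    else:
        expected = present  # ISO-week labels don't align with period_range labels
    warnings = [f"window {w} contains no events; omitted" for w in expected if w not in present]

    roles = sorted(ROLES)
    counts: dict[tuple[str, str], int] = {}
    shares: dict[tuple[str, str], float] = {}
    grouped = df.groupby(["window", "role"]).size()
    totals = df.groupby("window").size()
    for w in present:
        total = int(totals[w])
        for r in roles:
            n = int(grouped.get((w, r), 0))
            counts[(w, r)] = n
            shares[(w, r)] = n / total
    return RoleActivityMatrix(
        windows=present, roles=roles, counts=counts, shares=shares, warnings=warnings
    )


def share_drift(matrix: RoleActivityMatrix, role: str) -> DriftRecord:
    """Summarize one role's share trajectory across the windows."""
    if role not in matrix.roles:
        raise KeyError(f"unknown role {role!r}; known: {matrix.roles}")
    if len(matrix.windows) < 2:
        raise ValueError("drift needs at least two windows")
    series = matrix.share_series(role)
    diffs = [b - a for a, b in zip(series, series[1:])]
    signs = [(d > 0) - (d < 0) for d in diffs]
    return DriftRecord(
        role=role,
        first_share=series[0],
        last_share=series[-1],
        change=series[-1] - series[0],
        diff_signs=signs,
    )


@dataclass
class HandoverNetwork:
    nodes: set[str]
    arcs: Counter  # (giver, receiver) -> handover count
    level: str

    @property
    def total_weight(self) -> int:
        return sum(self.arcs.values())

    def to_dot(self) -> str:
        lines = ["digraph handover {"]
        for (a, b), w in sorted(self.arcs.items()):
            lines.append(f'  "{a}" -> "{b}" [label="{w}"];')
        lines.append("}")
        return "\n".join(lines)


def handover_network(log: EventLog, level: str = "role") -> HandoverNetwork:
    """Directed handovers between consecutive events of each case.

    ``level`` selects the actor granularity: professional role or individual
    resource. Self-handovers are kept as self-loops, so the total arc weight
    equals sum over cases of (trace length - 1).
    """
    if len(log) == 0:
        raise EmptyInputError("log has no traces")
    if level not in ("role", "resource"):
        raise ValueError("level must be 'role' or 'resource'")
    arcs: Counter = Counter()
    nodes: set[str] = set()
    for tr in log:
        actors = [getattr(ev, level) for ev in tr.events]
        nodes.update(actors)
        for a, b in zip(actors, actors[1:]):
            arcs[(a, b)] += 1
    return HandoverNetwork(nodes=nodes, arcs=arcs, level=level)
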