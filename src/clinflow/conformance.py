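"""Workflow nets, token-based replay conformance, and process discovery.

Conformance checking compares each observed trace against a reference
workflow net (a Petri net with one source and one sink place) by replaying
its events as transition firings and counting tokens:

* p — produced tokens, including the single token placed on the source
  before replay begins;
* c — consumed tokens, including the final consumption from the sink;
* m — missing tokens that had to be created to fire a transition whose
  input place was empty;
* r — remaining tokens left on places after the sink token is consumed.

The per-trace fitness is the standard token-replay definition

    fitness = 1/2 * (1 - m/c) + 1/2 * (1 - r/p)  in [0, 1],

equal to 1 exactly when the trace is in the net's language. Events whose
label matches no transition are skipped and logged (EMR exports carry
ancillary events); ``strict=True`` turns each into a one-missing/one-consumed
penalty instead.

Process discovery here is the directly-follows graph: immediate-succession
counts across all traces, the simplest frequent-pathway map.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .eventlog import EmptyInputError, EventLog, Trace

__all__ = [
    "WorkflowNet",
    "ReplayResult",
    "ConformanceResult",
    "DirectlyFollowsGraph",
    "sequence_model",
    "token_replay",
    "log_conformance",
    "discover_dfg",
]


@dataclass
class WorkflowNet:
    """A place/transition net with a single source and a single sink place.

    ``transitions`` maps transition id -> activity label; ``arcs`` are
    directed (place -> transition) or (transition -> place) pairs.
    """

    places: set[str]
    transitions: dict[str, str]
    arcs: set[tuple[str, str]]
    source: str
    sink: str

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nodes = self.places | set(self.transitions)
        for src, dst in self.arcs:
            if src not in nodes or dst not in nodes:
                raise ValueError(f"arc ({src!r}, {dst!r}) references unknown node")
            if (src in self.places) == (dst in self.places):
                raise ValueError(f"arc ({src!r}, {dst!r}) must connect place and transition")
        incoming = {dst for _, dst in self.arcs}
        outgoing = {src for src, _ in self.arcs}
        sources = [p for p in self.places if p not in incoming]
        sinks = [p for p in self.places if p not in outgoing]
        if set(sources) != {self.source}:
            raise ValueError(f"expected unique source {self.source!r}, found {sources}")
        if set(sinks) != {self.sink}:
            raise ValueError(f"expected unique sink {self.sink!r}, found {sinks}")

    def inputs(self, transition: str) -> list[str]:
        return sorted(src for src, dst in self.arcs if dst == transition)

    def outputs(self, transition: str) -> list[str]:
        return sorted(dst for src, dst in self.arcs if src == transition)

    def transitions_for_label(self, label: str) -> list[str]:
        return sorted(tid for tid, lab in self.transitions.items() if lab == label)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "places": sorted(self.places),
            "transitions": [{"id": tid, "label": lab} for tid, lab in sorted(self.transitions.items())],
            "arcs": sorted([list(a) for a in self.arcs]),
            "source": self.source,
            "sink": self.sink,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "WorkflowNet":
        data = json.loads(Path(path).read_text())
        return cls(
            places=set(data["places"]),
            transitions={t["id"]: t["label"] for t in data["transitions"]},
            arcs={tuple(a) for a in data["arcs"]},
            source=data["source"],
            sink=data["sink"],
        )


def sequence_model(activities: Sequence[str]) -> WorkflowNet:
    """Linear net place -> transition -> place ... for an ordered pathway.

    n activities give n transitions and n+1 places, with the outer places as
    source and sink.
    """
    if not activities:
        raise ValueError("activity list must be non-empty")
    if len(set(activities)) != len(activities):
        raise ValueError("activity labels must be duplicate-free")
    places = {f"p{i}" for i in range(len(activities) + 1)}
    transitions = {f"t{i}": act for i, act in enumerate(activities)}
    arcs: set[tuple[str, str]] = set()
    for i in range(len(activities)):
        arcs.add((f"p{i}", f"t{i}"))
        arcs.add((f"t{i}", f"p{i + 1}"))
    return WorkflowNet(
        places=places,
        transitions=transitions,
        arcs=arcs,
        source="p0",
        sink=f"p{len(activities)}",
    )


@dataclass
class ReplayResult:
    produced: int
    consumed: int
    missing: int
    remaining: int
    unmapped: list[str] = field(default_factory=list)

    @property
    def fitness(self) -> float:
        half_m = 1.0 - self.missing / self.consumed if self.consumed else 1.0
        half_r = 1.0 - self.remaining / self.produced if self.produced else 1.0
        return 0.5 * half_m + 0.5 * half_r


def token_replay(
    trace: Trace | Sequence[str],
    net: WorkflowNet,
    strict: bool = False,
) -> ReplayResult:
    """Replay one trace through the net and count p, c, m, r.

    A token is produced on the source before replay (counted in p); each
    event fires the transition carrying its label, consuming one token per
    input place (creating a missing token when the place is empty) and
    producing one per output place; finally one token is consumed from the
    sink (missing if absent). Remaining tokens after that final consumption
    are counted in r.
    """
    labels = trace.activities if isinstance(trace, Trace) else list(trace)
    marking: Counter[str] = Counter()
    produced = consumed = missing = 0

    marking[net.source] += 1
    produced += 1

    unmapped: list[str] = []
    for label in labels:
        tids = net.transitions_for_label(label)
        if not tids:
            unmapped.append(label)
            if strict:
                missing += 1
                consumed += 1
            continue
        tid = tids[0]
        for place in net.inputs(tid):
            if marking[place] < 1:
                missing += 1
                marking[place] += 1
            marking[place] -= 1
            consumed += 1
        for place in net.outputs(tid):
            marking[place] += 1
            produced += 1

    if marking[net.sink] < 1:
        missing += 1
        marking[net.sink] += 1
    marking[net.sink] -= 1
    consumed += 1

    remaining = sum(marking.values())
    return ReplayResult(
        produced=produced,
        consumed=consumed,
        missing=missing,
        remaining=remaining,
        unmapped=unmapped,
    )


@dataclass
class ConformanceResult:
    per_case: dict[str, ReplayResult]
    histogram: dict[str, int]
    mean_fitness: float
    n_cases: int
    bin_width: float

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "n_cases": self.n_cases,
            "mean_fitness": self.mean_fitness,
            "bin_width": self.bin_width,
            "histogram": self.histogram,
            "per_case": {
                cid: {
                    "produced": r.produced,
                    "consumed": r.consumed,
                    "missing": r.missing,
                    "remaining": r.remaining,
                    "fitness": r.fitness,
                }
                for cid, r in self.per_case.items()
            },
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _histogram(fitnesses: Iterable[float], bin_width: float) -> dict[str, int]:
    # right-open bins [0, w), [w, 2w), ...; fitness 1.0 falls in the top bin
    n_bins = int(round(1.0 / bin_width))
    counts = {i: 0 for i in range(n_bins)}
    for f in fitnesses:
        idx = min(int(f / bin_width), n_bins - 1)
        counts[idx] += 1
    return {
        f"[{i * bin_width:.2f},{(i + 1) * bin_width:.2f})": counts[i] for i in range(n_bins)
    }


def log_conformance(
    log: EventLog, net: WorkflowNet, bin_width: float = 0.1, strict: bool = False
) -> ConformanceResult:
    """Replay every case and summarize fitness as a histogram + mean."""
    if len(log) == 0:
        raise EmptyInputError("cannot assess conformance of an empty log")
    per_case = {tr.case_id: token_replay(tr, net, strict=strict) for tr in log}
    fitnesses = [r.fitness for r in per_case.values()]
    return ConformanceResult(
        per_case=per_case,
        histogram=_histogram(fitnesses, bin_width),
        mean_fitness=sum(fitnesses) / len(fitnesses),
        n_cases=len(fitnesses),
        bin_width=bin_width,
    )


@dataclass
class DirectlyFollowsGraph:
    nodes: set[str]
    arcs: Counter  # (a, b) -> immediate-succession count
    start_counts: Counter
    end_counts: Counter

    def to_dot(self) -> str:
        lines = ["digraph dfg {"]
        for (a, b), w in sorted(self.arcs.items()):
            lines.append(f'  "{a}" -> "{b}" [label="{w}"];')
        lines.append("}")
        return "\n".join(lines)


def discover_dfg(log: EventLog) -> DirectlyFollowsGraph:
    """Directly-follows graph: counts of immediate activity successions."""
    if len(log) == 0:
        raise EmptyInputError("cannot discover a process map from an empty log")
    arcs: Counter = Counter()
    starts: Counter = Counter()
    ends: Counter = Counter()
    nodes: set[str] = set()
    for tr in log:
        acts = tr.activities
        nodes.update(acts)
        if not acts:
            continue
        starts[acts[0]] += 1
        ends[acts[-1]] += 1
        for a, b in zip(acts, acts[1:]):
            arcs[(a, b)] += 1
    return DirectlyFollowsGraph(nodes=nodes, arcs=arcs, start_counts=starts, end_counts=ends)
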