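"""Shannon entropy of network degree distributions.

A department is modelled as a growing network of team members, artifacts
(machines, planning software) and information items (protocols, publications,
guidelines). The heterogeneity of its connectivity is summarized by the
Shannon entropy of the node-degree distribution,

    H = -sum_k p(k) * log2 p(k),      p(k) = n_k / n_nodes,

where n_k is the number of nodes of degree k. A regular network (one degree
class, like a rigidly ordered department) has H = 0; the entropy grows as
connectivity becomes more heterogeneous. Logarithms are base 2 (bits); the
base only rescales H and leaves every ratio and ordering unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

__all__ = [
    "NODE_KINDS",
    "EmptyNetworkError",
    "NetworkSnapshot",
    "DegreeDistribution",
    "EntropyResult",
    "EntropySeries",
    "degree_distribution",
    "shannon_entropy",
    "entropy_series",
]

NODE_KINDS = ("team", "artifact", "information")


class EmptyNetworkError(ValueError):
    """The snapshot has no nodes, so p(k) is undefined."""


@dataclass
class NetworkSnapshot:
    """An undirected simple graph at one point in time.

    Self-loops are rejected; parallel edges collapse (simple graph). Node
    kinds distinguish people from artifacts and information but do not enter
    the entropy, which depends on degrees only.
    """

    label: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(
        cls,
        label: str,
        nodes: Mapping[str, str] | Iterable[str],
        edges: Iterable[tuple[str, str]],
    ) -> "NetworkSnapshot":
        g = nx.Graph()
        if isinstance(nodes, Mapping):
            for nid, kind in nodes.items():
                g.add_node(nid, kind=kind)
        else:
            for nid in nodes:
                g.add_node(nid, kind="team")
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r} not allowed")
            if u not in g or v not in g:
                raise ValueError(f"edge ({u!r}, {v!r}) references unknown node")
            g.add_edge(u, v)
        return cls(label=label, graph=g)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class DegreeDistribution:
    """Tally n_k of nodes per degree k. Isolated nodes count at k = 0."""

    counts: dict[int, int]
    total_nodes: int

    def probabilities(self) -> dict[int, float]:
        return {k: n / self.total_nodes for k, n in self.counts.items()}


@dataclass
class EntropyResult:
    H: float  # bits
    p: dict[int, float]
    n_distinct_degrees: int


@dataclass
class EntropySeries:
    points: list[tuple[str, float]]
    ratio_last_first: float | None  # None when H_first == 0

    @property
    def values(self) -> list[float]:
        return [h for _, h in self.points]


def degree_distribution(net: NetworkSnapshot) -> DegreeDistribution:
    """Tally how many nodes have each degree."""
    if net.n_nodes == 0:
        raise EmptyNetworkError(f"snapshot {net.label!r} has no nodes")
    counts: dict[int, int] = {}
    for _, k in net.graph.degree():
        counts[k] = counts.get(k, 0) + 1
    return DegreeDistribution(counts=counts, total_nodes=net.n_nodes)


def shannon_entropy(dist: DegreeDistribution) -> EntropyResult:
    """H = -sum p(k) log2 p(k), with 0 log 0 := 0."""
    if dist.total_nodes < 1:
        raise EmptyNetworkError("degree distribution over zero nodes")
    p = dist.probabilities()
    h = -sum(pk * math.log2(pk) for pk in p.values() if pk > 0.0)
    # -0.0 from a single degree class reads poorly in reports
    return EntropyResult(H=abs(h), p=p, n_distinct_degrees=len(p))


def entropy_series(nets: Sequence[NetworkSnapshot]) -> EntropySeries:
    """Per-snapshot entropy in input order, plus the last/first ratio.

    The ratio H_last / H_first tracks how many-fold the structural complexity
    grew over the observed period; it is None when the first snapshot is
    regular (H_first = 0).
    """
    if not nets:
        raise EmptyNetworkError("empty snapshot sequence")
    points = [(net.label, shannon_entropy(degree_distribution(net)).H) for net in nets]
    h_first, h_last = points[0][1], points[-1][1]
    ratio = (h_last / h_first) if h_first > 0 else None
    return EntropySeries(points=points, ratio_last_first=ratio)
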