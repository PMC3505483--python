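"""Three-factor edge weighting: relevance x informativeness x reliability.

Each edge gets weight p(e) = q(e) * i(e) * r(e) where q is a per-edge-type
relevance coefficient, i(u,v) = deg(u)^-alpha * deg(v)^-alpha penalizes hub
nodes, and r is the source-database reliability.  Probabilistic proximity
measures need weights in [0,1], so a capped variant min(q*i*r, 1) is used for
them; the random walk uses the uncapped product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

from .graph_model import Edge, EdgeTypeRegistry, HeteroGraph

LINKTYPE_INDEPENDENT = "linktype_independent"
LINKTYPE_SPECIFIC = "linktype_specific"

#: Default degree-penalty exponent.
DEFAULT_ALPHA = 0.25


class ConfigError(Exception):
    pass


@dataclass(frozen=True)
class RelevanceMap:
    """Edge-type -> relevance coefficient q_tau in [0, inf).

    An edge type and its inverse resolve to the same value; unlisted types
    fall back to ``default_relevance``.
    """

    values: Mapping[str, float] = field(default_factory=dict)
    default_relevance: float = 1.0

    def __post_init__(self) -> None:
        if self.default_relevance < 0:
            raise ConfigError("default relevance must be non-negative")
        for t, v in self.values.items():
            if v < 0:
                raise ConfigError(f"negative relevance {v} for edge type {t!r}")

    def resolve(self, edge_type: str, registry: EdgeTypeRegistry) -> float:
        if edge_type in self.values:
            return self.values[edge_type]
        inv = registry.inverse(edge_type)
        if inv in self.values:
            return self.values[inv]
        return self.default_relevance

    def with_value(self, edge_type: str, value: float) -> "RelevanceMap":
        return RelevanceMap({**self.values, edge_type: value}, self.default_relevance)


@dataclass(frozen=True)
class WeightingConfig:
    alpha: float = DEFAULT_ALPHA
    degree_mode: str = LINKTYPE_INDEPENDENT
    cap: bool = True
    relevance: RelevanceMap = field(default_factory=RelevanceMap)

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigError(f"alpha {self.alpha} outside [0,1]")
        if self.degree_mode not in (LINKTYPE_INDEPENDENT, LINKTYPE_SPECIFIC):
            raise ConfigError(f"unknown degree mode {self.degree_mode!r}")

    @classmethod
    def from_json(cls, path) -> "WeightingConfig":
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            alpha=d.get("alpha", DEFAULT_ALPHA),
            degree_mode=d.get("degree_mode", LINKTYPE_INDEPENDENT),
            cap=d.get("cap", True),
            relevance=RelevanceMap(
                d.get("relevance", {}), d.get("default_relevance", 1.0)
            ),
        )

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "alpha": self.alpha,
                    "degree_mode": self.degree_mode,
                    "cap": self.cap,
                    "default_relevance": self.relevance.default_relevance,
                    "relevance": dict(self.relevance.values),
                },
                fh,
                indent=2,
            )


def informativeness(
    graph: HeteroGraph,
    edge: Edge,
    alpha: float = DEFAULT_ALPHA,
    degree_mode: str = LINKTYPE_INDEPENDENT,
) -> float:
    """Degree penalty i(u,v) = deg(u)^-alpha * deg(v)^-alpha in (0, 1].

    Degrees are taken on the unweighted topology.  In linktype-specific mode
    each endpoint counts only incident edges of the same type as this edge,
    oriented as seen from that endpoint.
    """
    if degree_mode == LINKTYPE_INDEPENDENT:
        du = graph.degree(edge.source)
        dv = graph.degree(edge.target)
    else:
        du = graph.degree(edge.source, edge.edge_type)
        dv = graph.degree(edge.target, graph.edge_types.inverse(edge.edge_type))
    return du ** (-alpha) * dv ** (-alpha)


def edge_weight(
    relevance: float, informativeness: float, reliability: float, cap: bool = True
) -> float:
    """Product combination q*i*r, optionally capped at 1."""
    w = relevance * informativeness * reliability
    return min(w, 1.0) if cap else w


@dataclass
class WeightedGraph:
    """A heterogeneous graph plus an edge -> weight mapping.

    ``cache`` holds per-graph solver state (e.g. the random-walk LU
    factorization); it is never part of equality or serialization.
    """

    graph: HeteroGraph
    weight: dict[Edge, float]
    cap: bool = True
    cache: dict = field(default_factory=dict, repr=False, compare=False)

    def w(self, edge: Edge) -> float:
        return self.weight.get(edge, 0.0)

    def subgraph(self, node_ids) -> "WeightedGraph":
        """Induced weighted subgraph; weights keep their full-graph values."""
        sub = self.graph.subgraph(node_ids)
        wts = {e: self.weight[e] for e in sub.edges()}
        return WeightedGraph(sub, wts, self.cap)


def apply_weights(graph: HeteroGraph, config: WeightingConfig) -> WeightedGraph:
    """Weight every edge of the graph per the three-factor scheme."""
    weights: dict[Edge, float] = {}
    for e in graph.edges():
        q = config.relevance.resolve(e.edge_type, graph.edge_types)
        i = informativeness(graph, e, config.alpha, config.degree_mode)
        weights[e] = edge_weight(q, i, e.reliability, config.cap)
    return WeightedGraph(graph, weights, config.cap)


def uniform_weights(graph: HeteroGraph, value: float = 1.0, cap: bool = True) -> WeightedGraph:
    """All edges at a fixed weight; handy for tests and degenerate limits."""
    return WeightedGraph(graph, {e: value for e in graph.edges()}, cap)


def save_weighted_edge_list(wg: WeightedGraph, path, header: bool = True) -> None:
    """Canonical TSV with a trailing weight column."""
    g = wg.graph
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(
                "source_id\tsource_type\tedge_type\ttarget_id\ttarget_type\t"
                "reliability\tweight\n"
            )
        for e in sorted(g.edges(), key=lambda e: (e.source, e.target, e.edge_type)):
            st = g.node(e.source).node_type
            tt = g.node(e.target).node_type
            fh.write(
                f"{e.source}\t{st}\t{e.edge_type}\t{e.target}\t{tt}\t"
                f"{e.reliability:g}\t{wg.w(e):.10g}\n"
            )
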