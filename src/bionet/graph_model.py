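"""Typed heterogeneous graph model and its TSV edge-list representation.

A graph holds typed nodes and typed, reliability-weighted edges.  Each edge
type has an inverse type (``codes_for`` / ``coded_by``); an edge is stored
once, in a canonical direction, and is queryable from either endpoint, the
reverse query reporting the inverse type.  Parallel edges between the same
node pair are collapsed, keeping the maximum reliability; self-loops are
rejected.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Callable, Iterable, Iterator, Mapping


class GraphError(Exception):
    """Base class for graph-model errors."""


class ParseError(GraphError):
    """Malformed edge-list row (carries a line number)."""


class SchemaError(GraphError):
    """Unregistered node or edge type."""


class LookupError_(GraphError):
    """Unknown node referenced in a query."""


@dataclass(frozen=True)
class NodeTypeRegistry:
    """Set of admissible node-type labels (Gene, Protein, Phenotype, ...)."""

    names: frozenset[str]

    def __post_init__(self) -> None:
        for n in self.names:
            if not n:
                raise SchemaError("node type labels must be non-empty")

    @classmethod
    def of(cls, *names: str) -> "NodeTypeRegistry":
        return cls(frozenset(names))

    def __contains__(self, name: str) -> bool:
        return name in self.names


class EdgeTypeRegistry:
    """Edge types and their inverses.

    Every type has exactly one inverse and the inverse of the inverse is the
    type itself; a symmetric type (``interacts_with``) is its own inverse.
    """

    def __init__(self, entries: Iterable[tuple[str, str]]):
        self._inverse: dict[str, str] = {}
        for t, inv in entries:
            if not t or not inv:
                raise SchemaError("edge type labels must be non-empty")
            for a, b in ((t, inv), (inv, t)):
                if a in self._inverse and self._inverse[a] != b:
                    raise SchemaError(f"conflicting inverse for edge type {a!r}")
                self._inverse[a] = b

    @classmethod
    def of(cls, *entries) -> "EdgeTypeRegistry":
        """Build from 'type' strings (symmetric) and (type, inverse) pairs."""
        norm = []
        for e in entries:
            norm.append((e, e) if isinstance(e, str) else tuple(e))
        return cls(norm)

    def inverse(self, edge_type: str) -> str:
        try:
            return self._inverse[edge_type]
        except KeyError:
            raise SchemaError(f"unregistered edge type {edge_type!r}") from None

    def __contains__(self, edge_type: str) -> bool:
        return edge_type in self._inverse

    @property
    def types(self) -> frozenset[str]:
        return frozenset(self._inverse)

    def canonical_types(self) -> list[str]:
        """One representative per {type, inverse} pair, sorted."""
        out = []
        for t, inv in sorted(self._inverse.items()):
            if t <= inv:
                out.append(t)
        return out

    @classmethod
    def load(cls, path) -> "EdgeTypeRegistry":
        entries = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                entries.append((parts[0], parts[1] if len(parts) > 1 else parts[0]))
        return cls(entries)


@dataclass(frozen=True)
class Node:
    id: str
    node_type: str
    attributes: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class Edge:
    """One stored (canonical-direction) relation with its reliability."""

    source: str
    target: str
    edge_type: str
    reliability: float = 1.0

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise GraphError(f"self-loop on node {self.source!r}")
        if not 0.0 <= self.reliability <= 1.0:
            raise ValueError(
                f"reliability {self.reliability} outside [0,1] "
                f"on edge {self.source}-{self.target}"
            )

    @property
    def key(self) -> frozenset:
        return frozenset((self.source, self.target))


@dataclass(frozen=True)
class IncidentEdge:
    """An edge as seen from one endpoint: type label oriented outward."""

    neighbor: str
    edge_type: str
    reliability: float
    edge: Edge


class HeteroGraph:
    """Undirected heterogeneous graph with directed edge-type labels.

    Edges are stored once per unordered node pair.  The canonical storage
    direction is the one with the lexicographically smaller
    ``(source_type, edge_type, source_id)`` tuple; this is invisible through
    the query API, which reports the correctly oriented type from either
    endpoint.
    """

    def __init__(
        self,
        node_types: NodeTypeRegistry,
        edge_types: EdgeTypeRegistry,
    ):
        self.node_types = node_types
        self.edge_types = edge_types
        self._nodes: dict[str, Node] = {}
        self._adj: dict[str, dict[str, Edge]] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, node_id: str, node_type: str, **attributes: str) -> Node:
        if node_type not in self.node_types:
            raise SchemaError(f"unregistered node type {node_type!r}")
        existing = self._nodes.get(node_id)
        if existing is not None:
            if existing.node_type != node_type:
                raise SchemaError(
                    f"node {node_id!r} redeclared with type {node_type!r} "
                    f"(was {existing.node_type!r})"
                )
            return existing
        node = Node(node_id, node_type, attributes)
        self._nodes[node_id] = node
        self._adj[node_id] = {}
        return node

    def add_edge(
        self, source: str, target: str, edge_type: str, reliability: float = 1.0
    ) -> Edge:
        """Add (or collapse into) the edge between two existing nodes.

        A duplicate unordered pair keeps the maximum reliability.  The row may
        name the relation by either its type or its inverse; it is stored in
        canonical direction.
        """
        if edge_type not in self.edge_types:
            raise SchemaError(f"unregistered edge type {edge_type!r}")
        for nid in (source, target):
            if nid not in self._nodes:
                raise LookupError_(f"unknown node {nid!r}")
        if source == target:
            raise GraphError(f"self-loop on node {source!r}")

        inv = self.edge_types.inverse(edge_type)
        fwd = (self._nodes[source].node_type, edge_type, source)
        rev = (self._nodes[target].node_type, inv, target)
        if rev < fwd:
            source, target, edge_type = target, source, inv

        prev = self._adj[source].get(target)
        if prev is not None:
            reliability = max(reliability, prev.reliability)
        edge = Edge(source, target, edge_type, reliability)
        self._adj[source][target] = edge
        self._adj[target][source] = edge
        return edge

    def remove_node(self, node_id: str) -> None:
        for nbr in list(self._adj[node_id]):
            del self._adj[nbr][node_id]
        del self._adj[node_id]
        del self._nodes[node_id]

    def remove_edge(self, u: str, v: str) -> None:
        del self._adj[u][v]
        del self._adj[v][u]

    # -- queries ----------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node(self, node_id: str) -> Node:
        try:
            return self._nodes[node_id]
        except KeyError:
            raise LookupError_(f"unknown node {node_id!r}") from None

    @property
    def nodes(self) -> list[Node]:
        return list(self._nodes.values())

    @property
    def node_ids(self) -> list[str]:
        return list(self._nodes)

    def edges(self) -> Iterator[Edge]:
        """Each stored relation exactly once, in canonical direction."""
        for u, nbrs in self._adj.items():
            for v, e in nbrs.items():
                if e.source == u:
                    yield e

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return sum(1 for _ in self.edges())

    def incident(self, node_id: str) -> list[IncidentEdge]:
        """Edges at a node, each typed as seen from that node."""
        if node_id not in self._nodes:
            raise LookupError_(f"unknown node {node_id!r}")
        out = []
        for nbr, e in self._adj[node_id].items():
            etype = e.edge_type if e.source == node_id else self.edge_types.inverse(e.edge_type)
            out.append(IncidentEdge(nbr, etype, e.reliability, e))
        return out

    def get_edge(self, u: str, v: str) -> IncidentEdge | None:
        """The relation from u to v as seen from u, or None."""
        for nid in (u, v):
            if nid not in self._nodes:
                raise LookupError_(f"unknown node {nid!r}")
        e = self._adj[u].get(v)
        if e is None:
            return None
        etype = e.edge_type if e.source == u else self.edge_types.inverse(e.edge_type)
        return IncidentEdge(v, etype, e.reliability, e)

    def neighbors(self, node_id: str) -> list[str]:
        if node_id not in self._nodes:
            raise LookupError_(f"unknown node {node_id!r}")
        return list(self._adj[node_id])

    def degree(self, node_id: str, edge_type: str | None = None) -> int:
        """Incident undirected relations, each counted once.

        With ``edge_type``, only edges whose type *as seen from this node*
        equals the label are counted (the linktype-specific degree).
        """
        if node_id not in self._nodes:
            raise LookupError_(f"unknown node {node_id!r}")
        if edge_type is None:
            return len(self._adj[node_id])
        return sum(1 for ie in self.incident(node_id) if ie.edge_type == edge_type)

    # -- derived graphs ---------------------------------------------------

    def copy(self) -> "HeteroGraph":
        g = HeteroGraph(self.node_types, self.edge_types)
        g._nodes = dict(self._nodes)
        g._adj = {u: dict(nbrs) for u, nbrs in self._adj.items()}
        return g

    def subgraph(self, node_ids: Iterable[str]) -> "HeteroGraph":
        keep = set(node_ids)
        g = HeteroGraph(self.node_types, self.edge_types)
        for nid in keep:
            g._nodes[nid] = self.node(nid)
            g._adj[nid] = {}
        for e in self.edges():
            if e.source in keep and e.target in keep:
                g._adj[e.source][e.target] = e
                g._adj[e.target][e.source] = e
        return g

    def filter_graph(
        self,
        drop_node_types: Iterable[str] = (),
        drop_edge_types: Iterable[str] = (),
        drop_sources: Callable[[Node], bool] | None = None,
    ) -> "HeteroGraph":
        """Copy with matching nodes (plus incident edges) and edges removed.

        ``drop_edge_types`` matches either orientation of a type.  This is the
        reduced-data operation: e.g. drop all Phenotype nodes, or all edges of
        a given provenance via the node predicate.
        """
        dnt = set(drop_node_types)
        det = set()
        for t in drop_edge_types:
            det.add(t)
            det.add(self.edge_types.inverse(t))
        g = self.copy()
        for node in list(g.nodes):
            if node.node_type in dnt or (drop_sources is not None and drop_sources(node)):
                g.remove_node(node.id)
        if det:
            for e in list(g.edges()):
                if e.edge_type in det:
                    g.remove_edge(e.source, e.target)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HeteroGraph):
            return NotImplemented
        return self._nodes == other._nodes and set(self.edges()) == set(other.edges())


# -- neighborhood bounding -------------------------------------------------


def neighborhood_subgraph(
    graph: HeteroGraph,
    terminals: Iterable[str],
    max_nodes: int,
    max_depth: int,
    weight: Mapping[Edge, float] | None = None,
) -> HeteroGraph:
    """Induced subgraph around terminal nodes, for bounding expensive measures.

    Keeps nodes reachable from any terminal within ``max_depth`` hops,
    truncated to the ``max_nodes`` nodes with the highest best-path probability
    to the nearest terminal (ties broken by node id); terminals are always
    retained.  Best-path probabilities use ``weight`` if given, else edge
    reliabilities.
    """
    terminals = list(terminals)
    for t in terminals:
        if t not in graph:
            raise LookupError_(f"unknown terminal {t!r}")
    if max_nodes < len(terminals):
        raise ValueError("max_nodes must be at least the number of terminals")

    def w(e: Edge) -> float:
        return e.reliability if weight is None else weight.get(e, 0.0)

    # hop-limited BFS for reachability
    depth: dict[str, int] = {t: 0 for t in terminals}
    frontier = deque(terminals)
    while frontier:
        u = frontier.popleft()
        if depth[u] == max_depth:
            continue
        for v in graph.neighbors(u):
            if v not in depth:
                depth[v] = depth[u] + 1
                frontier.append(v)

    # multi-source Dijkstra on -log(weight) within the reachable set
    best: dict[str, float] = {}
    heap: list[tuple[float, str]] = [(0.0, t) for t in terminals]
    while heap:
        d, u = heappop(heap)
        if u in best:
            continue
        best[u] = d
        for ie in graph.incident(u):
            v, pw = ie.neighbor, w(ie.edge)
            if v in best or v not in depth or pw <= 0.0:
                continue
            heappush(heap, (d - math.log(pw), v))

    reachable = set(depth)
    tset = set(terminals)
    # rank non-terminals by best-path probability (prob = exp(-d)), ties by id
    ranked = sorted(
        (n for n in reachable if n not in tset),
        key=lambda n: (best.get(n, math.inf), n),
    )
    keep = list(tset) + ranked[: max_nodes - len(tset)]
    return graph.subgraph(keep)


# -- TSV edge-list I/O -----------------------------------------------------

_HEADER = "source_id\tsource_type\tedge_type\ttarget_id\ttarget_type\treliability"


def load_edge_list(
    path,
    edge_types: EdgeTypeRegistry,
    node_types: NodeTypeRegistry | None = None,
) -> HeteroGraph:
    """Parse a TSV edge list into a validated graph.

    Columns: source_id, source_type, edge_type, target_id, target_type,
    reliability (optional, default 1.0).  '#'-prefixed lines and an optional
    header row are skipped.  If ``node_types`` is omitted, the registry is
    inferred from the file.
    """
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if parts[:5] == _HEADER.split("\t")[:5]:
                continue
            if len(parts) not in (5, 6):
                raise ParseError(f"{path}:{lineno}: expected 5 or 6 columns, got {len(parts)}")
            rows.append((lineno, parts))

    if node_types is None:
        node_types = NodeTypeRegistry(frozenset(p[1] for _, p in rows) | frozenset(p[4] for _, p in rows))

    g = HeteroGraph(node_types, edge_types)
    for lineno, p in rows:
        sid, stype, etype, tid, ttype = p[:5]
        if len(p) == 6:
            try:
                rel = float(p[5])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad reliability {p[5]!r}") from None
        else:
            rel = 1.0
        if not 0.0 <= rel <= 1.0:
            raise ValueError(f"{path}:{lineno}: reliability {rel} outside [0,1]")
        try:
            g.add_node(sid, stype)
            g.add_node(tid, ttype)
            g.add_edge(sid, tid, etype, rel)
        except (SchemaError, GraphError) as exc:
            raise type(exc)(f"{path}:{lineno}: {exc}") from None
    return g


def save_edge_list(graph: HeteroGraph, path, header: bool = True) -> None:
    """Write the canonical TSV edge list (round-trips with load_edge_list)."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(_HEADER + "\n")
        for e in sorted(graph.edges(), key=lambda e: (e.source, e.target, e.edge_type)):
            st = graph.node(e.source).node_type
            tt = graph.node(e.target).node_type
            fh.write(f"{e.source}\t{st}\t{e.edge_type}\t{e.target}\t{tt}\t{e.reliability:g}\n")
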