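"""Weighted labeled property graph built from quintuple assertions.

A quintuple (SUB, SUBT, Rr, OBJ, OBJT) is the atomic knowledge unit; it is
direction-asymmetric by definition.  Node identity is the pair
(name, category): the same surface name may legitimately appear as both a
disease and a symptom.  Re-asserting an existing (subject, relation, object)
triple increments the edge's occurrence weight instead of storing a
duplicate, so edge weight equals the number of supporting quintuple rows.

Edges are stored as doubly linked edge records: each node holds a pointer to
its first incident edge, and every edge carries previous/next pointers for
both its start-node list (sp/sn) and its end-node list (ep/en).  Scanning a
node's incident edges therefore never touches edges of other nodes.  The
linked layout is an internal contract (checked against a full-scan oracle in
the test suite), not a serialization format.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .ontology import canon

__all__ = [
    "Quintuple",
    "NodeRecord",
    "EdgeRecord",
    "PropertyGraph",
    "EdgeNotFoundError",
    "NodeNotFoundError",
    "ingest_quintuples",
    "edge_weight",
    "grade_weights",
    "linked_edge_scan",
]


class NodeNotFoundError(KeyError):
    pass


class EdgeNotFoundError(KeyError):
    pass


@dataclass(frozen=True)
class EntitySpan:
    """Candidate entity span over a tokenized sentence (1-based, inclusive)."""

    text: str
    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid span bounds ({self.start}, {self.end})")


@dataclass
class Quintuple:
    sub: str
    sub_type: str
    rel: str
    obj: str
    obj_type: str
    attributes: Dict[str, str] = field(default_factory=dict)
    sub_attrs: Dict[str, str] = field(default_factory=dict)
    obj_attrs: Dict[str, str] = field(default_factory=dict)
    rel_label: str = ""

    def __post_init__(self):
        for name in ("sub", "sub_type", "rel", "obj", "obj_type"):
            if not str(getattr(self, name)).strip():
                raise ValueError(f"quintuple field {name!r} is empty")

    def key(self) -> Tuple[str, str, str, str, str]:
        return (self.sub, self.sub_type, self.rel, self.obj, self.obj_type)


@dataclass
class NodeRecord:
    node_id: int
    name: str
    category: str
    attributes: Dict[str, str] = field(default_factory=dict)
    first_edge: Optional[int] = None


@dataclass
class EdgeRecord:
    edge_id: int
    start_node: int
    end_node: int
    label: str
    weight: int = 1
    attributes: Dict[str, str] = field(default_factory=dict)
    sp: Optional[int] = None  # previous edge in start node's list
    sn: Optional[int] = None  # next edge in start node's list
    ep: Optional[int] = None  # previous edge in end node's list
    en: Optional[int] = None  # next edge in end node's list


class PropertyGraph:
    """Session-scoped property graph with frequency-weighted directed edges."""

    def __init__(self):
        self._nodes: Dict[int, NodeRecord] = {}
        self._edges: Dict[int, EdgeRecord] = {}
        self._node_index: Dict[Tuple[str, str], int] = {}
        self._edge_index: Dict[Tuple[int, str, int], int] = {}
        self._last_edge: Dict[int, Optional[int]] = {}
        self.weight_tiers: Dict[int, int] = {}
        self.notes: List[str] = []
        self._next_node = 0
        self._next_edge = 0

    # -- nodes ------------------------------------------------------------
    def nodes(self) -> List[NodeRecord]:
        return [self._nodes[i] for i in sorted(self._nodes)]

    def edges(self) -> List[EdgeRecord]:
        return [self._edges[i] for i in sorted(self._edges)]

    def node(self, node_id: int) -> NodeRecord:
        return self._nodes[node_id]

    def edge(self, edge_id: int) -> EdgeRecord:
        return self._edges[edge_id]

    def find_node(self, name: str, category: Optional[str] = None) -> NodeRecord:
        """Resolve a node by name, optionally disambiguated by category."""
        if category is not None:
            nid = self._node_index.get((canon(name), canon(category)))
            if nid is None:
                raise NodeNotFoundError(f"no node {name!r} [{category}]")
            return self._nodes[nid]
        hits = [
            self._nodes[i]
            for (n, _c), i in self._node_index.items()
            if n == canon(name)
        ]
        if not hits:
            raise NodeNotFoundError(f"no node named {name!r}")
        if len(hits) > 1:
            cats = sorted(h.category for h in hits)
            raise NodeNotFoundError(
                f"node name {name!r} is ambiguous across categories {cats}; "
                "pass a category"
            )
        return hits[0]

    def has_node(self, name: str, category: str) -> bool:
        return (canon(name), canon(category)) in self._node_index

    def add_node(self, name: str, category: str,
                 attributes: Optional[Dict[str, str]] = None) -> int:
        key = (canon(name), canon(category))
        nid = self._node_index.get(key)
        if nid is None:
            nid = self._next_node
            self._next_node += 1
            self._nodes[nid] = NodeRecord(nid, name.strip(), category.strip(),
                                          dict(attributes or {}))
            self._node_index[key] = nid
            self._last_edge[nid] = None
        elif attributes:
            node = self._nodes[nid]
            for k, v in attributes.items():
                if k in node.attributes and node.attributes[k] != v:
                    self.notes.append(
                        f"attribute conflict on {node.name!r} [{node.category}]: "
                        f"{k}={node.attributes[k]!r} overwritten by {v!r}"
                    )
                node.attributes[k] = v
        return nid

    # -- edges ------------------------------------------------------------
    def _append_to_list(self, node_id: int, edge: EdgeRecord) -> None:
        tail = self._last_edge[node_id]
        if tail is None:
            self._nodes[node_id].first_edge = edge.edge_id
        else:
            t = self._edges[tail]
            if t.start_node == node_id:
                t.sn = edge.edge_id
            else:
                t.en = edge.edge_id
            if edge.start_node == node_id:
                edge.sp = tail
            else:
                edge.ep = tail
        self._last_edge[node_id] = edge.edge_id

    def add_edge(self, start: int, label: str, end: int, weight: int = 1,
                 attributes: Optional[Dict[str, str]] = None) -> int:
        key = (start, canon(label), end)
        eid = self._edge_index.get(key)
        if eid is not None:
            self._edges[eid].weight += weight
            if attributes:
                self._edges[eid].attributes.update(attributes)
            return eid
        eid = self._next_edge
        self._next_edge += 1
        edge = EdgeRecord(eid, start, end, label.strip(), weight,
                          dict(attributes or {}))
        self._edges[eid] = edge
        self._edge_index[key] = eid
        self._append_to_list(start, edge)
        if end != start:
            self._append_to_list(end, edge)
        return eid

    def find_edge(self, sub_name: str, rel: str, obj_name: str,
                  sub_category: Optional[str] = None,
                  obj_category: Optional[str] = None) -> EdgeRecord:
        s = self.find_node(sub_name, sub_category)
        o = self.find_node(obj_name, obj_category)
        eid = self._edge_index.get((s.node_id, canon(rel), o.node_id))
        if eid is None:
            raise EdgeNotFoundError(
                f"no edge ({sub_name!r}, {rel!r}, {obj_name!r})"
            )
        return self._edges[eid]

    def incident_edges(self, node_id: int) -> List[EdgeRecord]:
        """Insertion-ordered incident edges via the linked edge records."""
        out, seen = [], set()
        eid = self._nodes[node_id].first_edge
        while eid is not None:
            if eid in seen:
                raise RuntimeError(
                    f"linked-list cycle at node {node_id}, edge {eid}"
                )
            seen.add(eid)
            edge = self._edges.get(eid)
            if edge is None:
                raise RuntimeError(f"dangling edge pointer {eid} at node {node_id}")
            out.append(edge)
            eid = edge.sn if edge.start_node == node_id else edge.en
        return out

    def neighbors(self, node_id: int) -> List[Tuple[int, EdgeRecord]]:
        """(other-node-id, edge) pairs in insertion order, both directions."""
        out = []
        for e in self.incident_edges(node_id):
            other = e.end_node if e.start_node == node_id else e.start_node
            out.append((other, e))
        return out

    # -- views ------------------------------------------------------------
    def to_networkx(self):
        import networkx as nx

        g = nx.MultiDiGraph()
        for n in self.nodes():
            g.add_node(n.node_id, name=n.name, category=n.category,
                       **{f"attr_{k}": v for k, v in n.attributes.items()})
        for e in self.edges():
            g.add_edge(e.start_node, e.end_node, label=e.label,
                       weight=e.weight,
                       **{f"attr_{k}": v for k, v in e.attributes.items()})
        return g

    def canonical_form(self) -> tuple:
        """Order-independent identity: names, categories, labels, weights."""
        nodes = sorted(
            (n.name, n.category, tuple(sorted(n.attributes.items())))
            for n in self.nodes()
        )
        edges = sorted(
            (
                self._nodes[e.start_node].name,
                self._nodes[e.start_node].category,
                e.label,
                self._nodes[e.end_node].name,
                self._nodes[e.end_node].category,
                e.weight,
                tuple(sorted(e.attributes.items())),
            )
            for e in self.edges()
        )
        return (tuple(nodes), tuple(edges))

    def total_weight(self) -> int:
        return sum(e.weight for e in self._edges.values())

    def __len__(self):
        return len(self._nodes)


# ---------------------------------------------------------------------------
# operations


def ingest_quintuples(rows: Iterable[Quintuple],
                      schema=None,
                      on_category_conflict: str = "fork") -> PropertyGraph:
    """Build a property graph from quintuple assertions.

    Duplicate (subject, relation, object) triples increment the stored
    edge's weight; node attributes merge last-writer-wins with a note logged
    on conflict.  ``on_category_conflict`` controls what happens when a name
    reappears under a different category: ``"fork"`` (default) keeps the two
    as distinct nodes, ``"reject"`` raises.  When a schema is given, each row
    is validated non-strictly and validation findings are logged to
    ``graph.notes``; content never aborts ingestion.
    """
    if on_category_conflict not in {"fork", "reject"}:
        raise ValueError("on_category_conflict must be 'fork' or 'reject'")
    from .ontology import validate_quintuple

    graph = PropertyGraph()
    name_cats: Dict[str, str] = {}
    for i, q in enumerate(rows, start=1):
        if schema is not None:
            report = validate_quintuple(q, schema, strict=False)
            for v in report.violations:
                graph.notes.append(f"row {i}: {v}")
        for name, cat in ((q.sub, q.sub_type), (q.obj, q.obj_type)):
            prev = name_cats.get(canon(name))
            if prev is not None and prev != canon(cat):
                if on_category_conflict == "reject":
                    raise ValueError(
                        f"row {i}: node {name!r} already exists with a "
                        f"different category"
                    )
                graph.notes.append(
                    f"row {i}: name {name!r} forked into category {cat!r}"
                )
            name_cats.setdefault(canon(name), canon(cat))
        s = graph.add_node(q.sub, q.sub_type, q.sub_attrs)
        o = graph.add_node(q.obj, q.obj_type, q.obj_attrs)
        graph.add_edge(s, q.rel, o, attributes=dict(q.attributes))
    return graph


def edge_weight(graph: PropertyGraph, sub_name: str, rel: str, obj_name: str,
                sub_category: Optional[str] = None,
                obj_category: Optional[str] = None) -> int:
    """Stored occurrence count of a directed (subject, relation, object) edge."""
    return graph.find_edge(sub_name, rel, obj_name, sub_category,
                           obj_category).weight


def grade_weights(graph: PropertyGraph, n_tiers: int) -> Dict[int, int]:
    """Assign each edge a 1-based weight tier (higher tier = higher weight).

    Tiers are quantile buckets over the *distinct* edge weights: the sorted
    distinct weights are split into at most ``n_tiers`` near-equal runs, so
    equal weights always share a tier and tier order follows weight order.
    Requesting more tiers than there are distinct weights collapses
    gracefully.
    """
    if n_tiers < 1:
        raise ValueError("n_tiers must be >= 1")
    if not graph.edges():
        raise ValueError("graph has no edges to grade")
    distinct = sorted({e.weight for e in graph.edges()})
    k = min(n_tiers, len(distinct))
    chunks = np.array_split(np.asarray(distinct), k)
    tier_of = {}
    for tier, chunk in enumerate(chunks, start=1):
        for w in chunk.tolist():
            tier_of[w] = tier
    graph.weight_tiers = {e.edge_id: tier_of[e.weight] for e in graph.edges()}
    return dict(graph.weight_tiers)


def linked_edge_scan(graph: PropertyGraph, node_name: str,
                     category: Optional[str] = None) -> List[EdgeRecord]:
    """Incident edges of a node by walking its doubly linked edge records."""
    node = graph.find_node(node_name, category)
    return graph.incident_edges(node.node_id)
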