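"""Graph reasoning over medication knowledge graphs.

Six read-only procedures, each returning an auditable structure whose every
edge exists in the source graph with its stored label and weight:

* connectivity subgraphs (bounded undirected reachability from seed nodes);
* multi-hop "one drug for multiple uses" indication discovery;
* weighted-critical-path mining of synergistic drug combinations;
* minimum spanning tree extraction of core dosing knowledge (MK-MST);
* symptom-intersection maps for comorbid symptoms;
* all-pairs shortest paths between comorbidities and their medications;
* stage-ordered retrieval of treatments along disease-stage chains.

Edge weights encode occurrence frequency, i.e. relationship importance, so
the "minimum" spanning tree is computed under edge cost 1/weight: the tree
retains high-frequency relations.  Unbounded path searches carry a default
``max_hops=6`` safety bound because simple-path enumeration is exponential.
"""

from __future__ import annotations

import heapq
import re
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from .kg_core import EdgeRecord, NodeNotFoundError, PropertyGraph
from .ontology import canon

__all__ = [
    "PathResult",
    "SpanningTreeResult",
    "IntersectionResult",
    "SynergyEntry",
    "StageReport",
    "StagedRetrievalResult",
    "ComorbidityResult",
    "CategoryError",
    "StageCycleError",
    "connectivity_subgraph",
    "multi_use_discovery",
    "synergy_critical_path",
    "mk_mst",
    "symptom_intersection",
    "comorbidity_shortest_paths",
    "staged_retrieval",
    "DEFAULT_MAX_HOPS",
]

DEFAULT_MAX_HOPS = 6


class CategoryError(ValueError):
    pass


class StageCycleError(ValueError):
    def __init__(self, cycle: List[str]):
        self.cycle = cycle
        super().__init__(f"Stage relation cycle: {' -> '.join(cycle)}")


def _group(key: str) -> str:
    k = canon(key)
    return k[:-1] if k.endswith("s") else k


DISEASE_LIKE = {_group(c) for c in ("diseases", "complications")}
SYMPTOM_LIKE = {_group("symptoms")}
COMBO_LIKE = {_group(c) for c in ("drug combinations", "combination medications")}
DRUG_LIKE = {_group(c) for c in ("drugs", "mt")} | COMBO_LIKE
TREATMENT_LIKE = {_group(c) for c in ("therapeutic approaches", "treatment methods")}
RESULT_LIKE = {_group(c) for c in ("results", "drug effects")}


def _in(category: str, bucket: Set[str]) -> bool:
    return _group(category) in bucket


@dataclass(frozen=True)
class PathEdge:
    start: str
    end: str
    label: str
    weight: int
    forward: bool  # True when traversed in stored direction


@dataclass
class PathResult:
    nodes: List[Tuple[str, str]]  # (name, category), in traversal order
    edges: List[PathEdge]
    hops: int
    total_weight: int

    def node_names(self) -> List[str]:
        return [n for n, _ in self.nodes]


@dataclass
class SpanningTreeResult:
    root: Tuple[str, str]
    edges: List[EdgeRecord]
    records: Dict[str, Dict[str, object]]
    adverse_reactions: Set[str]
    general: Dict[str, object]
    total_cost: float


@dataclass
class IntersectionResult:
    symptoms: List[str]
    shared: Dict[str, Dict[str, PathResult]]  # shared node -> symptom -> path
    unified_treatments: List[str]

    @property
    def shared_nodes(self) -> List[str]:
        return list(self.shared)


@dataclass
class SynergyEntry:
    target: Tuple[str, str]
    drug_set: FrozenSet[str]
    path: PathResult
    total_weight: int


@dataclass
class StageReport:
    stage: str
    treatment_methods: List[str]
    drugs: List[str]
    results: List[str]


@dataclass
class StagedRetrievalResult:
    order: List[StageReport]
    inter_stage_paths: List[PathResult]


@dataclass
class ComorbidityResult:
    paths: List[PathResult]
    n_unreachable: int


# ---------------------------------------------------------------------------
# shared traversal helpers


def _sort_key(graph: PropertyGraph, nid: int) -> Tuple[str, str]:
    node = graph.node(nid)
    return (node.name, node.category)


def _bfs_dist(graph: PropertyGraph, sources: Iterable[int],
              max_hops: Optional[int] = None,
              allowed=None) -> Dict[int, int]:
    """Undirected hop distances from the source set, optionally bounded and
    restricted to nodes for which ``allowed(node_id)`` holds (sources are
    always admitted)."""
    dist = {s: 0 for s in sources}
    queue = deque(dist)
    while queue:
        u = queue.popleft()
        if max_hops is not None and dist[u] >= max_hops:
            continue
        for v, _e in graph.neighbors(u):
            if v in dist:
                continue
            if allowed is not None and not allowed(v):
                continue
            dist[v] = dist[u] + 1
            queue.append(v)
    return dist


def _edge_between(graph: PropertyGraph, u: int, v: int) -> Tuple[EdgeRecord, bool]:
    """First-inserted stored edge joining u and v; bool marks u->v direction."""
    best = None
    for other, e in graph.neighbors(u):
        if other == v and (best is None or e.edge_id < best[0].edge_id):
            best = (e, e.start_node == u)
    if best is None:
        raise KeyError(f"no edge between node ids {u} and {v}")
    return best


def _path_result(graph: PropertyGraph, node_ids: Sequence[int]) -> PathResult:
    nodes = [(graph.node(i).name, graph.node(i).category) for i in node_ids]
    edges, total = [], 0
    for u, v in zip(node_ids, node_ids[1:]):
        e, fwd = _edge_between(graph, u, v)
        s, t = graph.node(e.start_node), graph.node(e.end_node)
        edges.append(PathEdge(s.name, t.name, e.label, e.weight, fwd))
        total += e.weight
    return PathResult(nodes, edges, len(edges), total)


def _lex_shortest_ids(graph: PropertyGraph, src: int, dst: int,
                      max_hops: Optional[int] = None,
                      allowed=None) -> Optional[List[int]]:
    """Minimum-hop path src..dst whose node-name sequence is lexicographically
    smallest; None when unreachable within the bound."""
    back = _bfs_dist(graph, [dst], max_hops, allowed)
    if src not in back or (max_hops is not None and back[src] > max_hops):
        return None
    path = [src]
    current = src
    while current != dst:
        d = back[current]
        candidates = [
            v for v, _e in graph.neighbors(current)
            if back.get(v, -1) == d - 1
            and (allowed is None or allowed(v) or v == dst)
        ]
        current = min(candidates, key=lambda n: _sort_key(graph, n))
        path.append(current)
    return path


def _subgraph(graph: PropertyGraph, node_ids: Set[int]) -> PropertyGraph:
    sub = PropertyGraph()
    id_map = {}
    for nid in sorted(node_ids):
        n = graph.node(nid)
        id_map[nid] = sub.add_node(n.name, n.category, dict(n.attributes))
    for e in graph.edges():
        if e.start_node in node_ids and e.end_node in node_ids:
            sub.add_edge(id_map[e.start_node], e.label, id_map[e.end_node],
                         weight=e.weight, attributes=dict(e.attributes))
    return sub


# ---------------------------------------------------------------------------
# 1. connectivity subgraph


def connectivity_subgraph(graph: PropertyGraph, seeds: Sequence[str],
                          allowed_categories: Optional[Iterable[str]] = None,
                          max_hops: int = DEFAULT_MAX_HOPS) -> PropertyGraph:
    """Induced subgraph of nodes within ``max_hops`` undirected hops of any
    seed, with traversal optionally restricted to the given categories
    (seeds are always included)."""
    if max_hops < 0:
        raise ValueError("max_hops must be >= 0")
    seed_ids = [graph.find_node(s).node_id for s in seeds]
    allowed = None
    if allowed_categories is not None:
        groups = {_group(c) for c in allowed_categories}
        allowed = lambda nid: _group(graph.node(nid).category) in groups
    dist = _bfs_dist(graph, seed_ids, max_hops, allowed)
    return _subgraph(graph, set(dist))


# ---------------------------------------------------------------------------
# 2. one drug for multiple uses


def multi_use_discovery(graph: PropertyGraph, drug: str,
                        max_hops: int = DEFAULT_MAX_HOPS
                        ) -> Dict[str, List[PathResult]]:
    """Disease and symptom nodes reachable from a drug-like node, each with a
    shortest witnessing simple path; keyed by target name, ordered by
    (hop count, descending path weight, name)."""
    start = graph.find_node(drug)
    if not _in(start.category, DRUG_LIKE):
        raise CategoryError(
            f"{drug!r} has category {start.category!r}; expected a drug-like "
            "node (Drugs / MT / drug combination)"
        )
    dist = _bfs_dist(graph, [start.node_id], max_hops)
    found = []
    for nid, d in dist.items():
        if nid == start.node_id:
            continue
        node = graph.node(nid)
        if _in(node.category, DISEASE_LIKE | SYMPTOM_LIKE):
            ids = _lex_shortest_ids(graph, start.node_id, nid, max_hops)
            found.append((node.name, _path_result(graph, ids)))
    found.sort(key=lambda item: (item[1].hops, -item[1].total_weight, item[0]))
    out: Dict[str, List[PathResult]] = {}
    for name, path in found:
        out.setdefault(name, []).append(path)
    return out


# ---------------------------------------------------------------------------
# 3. weighted critical path synergy mining


def _layered_dag(graph: PropertyGraph, seed: int, max_hops: int
                 ) -> Tuple[Dict[int, int], Dict[int, List[Tuple[int, EdgeRecord]]]]:
    """Layer the seed's connectivity subgraph by BFS depth and keep only
    edges crossing from a shallower to a deeper layer (intra-layer edges are
    dropped).  Returns (layer map, DAG adjacency as predecessor lists)."""
    layer = _bfs_dist(graph, [seed], max_hops)
    preds: Dict[int, List[Tuple[int, EdgeRecord]]] = {n: [] for n in layer}
    for e in graph.edges():
        u, v = e.start_node, e.end_node
        if u not in layer or v not in layer:
            continue
        if layer[u] + 1 == layer[v]:
            preds[v].append((u, e))
        elif layer[v] + 1 == layer[u]:
            preds[u].append((v, e))
    return layer, preds


def max_weight_dag_path(graph: PropertyGraph, layer: Dict[int, int],
                        preds: Dict[int, List[Tuple[int, EdgeRecord]]],
                        seed: int) -> Tuple[Dict[int, int], Dict[int, int]]:
    """Maximum-total-weight path weights from the seed through the layered
    DAG (dynamic programming over layers; ties resolved toward the
    lexicographically smaller predecessor)."""
    dist: Dict[int, int] = {seed: 0}
    parent: Dict[int, int] = {}
    order = sorted(layer, key=lambda n: (layer[n],) + _sort_key(graph, n))
    for v in order:
        if v == seed:
            continue
        best = None
        for u, e in sorted(preds[v], key=lambda ue: _sort_key(graph, ue[0])):
            if u not in dist:
                continue
            cand = dist[u] + e.weight
            if best is None or cand > best[0]:
                best = (cand, u)
        if best is not None:
            dist[v], parent[v] = best
    return dist, parent


def synergy_critical_path(graph: PropertyGraph, disease: str,
                          max_hops: int = DEFAULT_MAX_HOPS
                          ) -> List[SynergyEntry]:
    """Rank drug-combination nodes around a disease by the maximum-weight
    path through the BFS-layered disease-drug DAG.

    Targets are combination-category nodes; when none is reachable the
    ranking falls back to plain drug nodes, so a bare disease—drug edge is
    its own critical path.  The drug set of an entry collects drug nodes on
    the critical path plus the member drugs of any drug-combination node on
    it, so a combination reached through a heavy "combined effect" edge
    reports its full membership.
    """
    seed = graph.find_node(disease).node_id
    layer, preds = _layered_dag(graph, seed, max_hops)
    dist, parent = max_weight_dag_path(graph, layer, preds, seed)

    reached = [n for n in dist if n != seed]
    targets = [n for n in reached if _in(graph.node(n).category, COMBO_LIKE)]
    if not targets:
        targets = [n for n in reached if _in(graph.node(n).category, DRUG_LIKE)]

    entries = []
    for nid in targets:
        w = dist[nid]
        node = graph.node(nid)
        ids = [nid]
        while ids[-1] != seed:
            ids.append(parent[ids[-1]])
        ids.reverse()
        path = _path_result(graph, ids)
        drugs: Set[str] = set()
        for pid in ids:
            p = graph.node(pid)
            if _group(p.category) == _group("drugs"):
                drugs.add(p.name)
            if _in(p.category, COMBO_LIKE):
                for other, _e in graph.neighbors(pid):
                    o = graph.node(other)
                    if _group(o.category) == _group("drugs"):
                        drugs.add(o.name)
        entries.append(SynergyEntry((node.name, node.category),
                                    frozenset(drugs), path, w))
    entries.sort(key=lambda s: (-s.total_weight, s.target[0]))
    return entries


# ---------------------------------------------------------------------------
# 4. MK-MST fine-grained medication extraction

_EXTRACT_CONCEPTS = {
    _group(c)
    for c in ("drug applications", "contraindications", "adverse reactions",
              "indications")
}

_DASH = r"[–—-]"
_DOSE_PATTERNS = [
    ("initial_dose", re.compile(r"initial dose (?:of )?(\d+(?:\.\d+)?\s*mg)", re.I)),
    ("max_dose", re.compile(r"maximum dos(?:age|e) (?:of )?(\d+(?:\.\d+)?\s*mg)", re.I)),
    ("dose_range", re.compile(
        rf"(?:dosage|dose) range (?:of )?(\d+\s*{_DASH}\s*\d+\s*mg)", re.I)),
    ("frequency", re.compile(rf"(\d+\s*(?:{_DASH}\s*\d+\s*)?times daily)", re.I)),
    ("form", re.compile(r"(tablet|capsule|injection|oral solution)(?:\s+form)?", re.I)),
    ("route", re.compile(r"(oral administration|intravenous(?: injection)?)", re.I)),
]


def parse_dosage(text: str) -> Dict[str, str]:
    """Extract dosing fields from an attribute-node name.

    One documented pattern family: "initial dose of N mg", "maximum dosage
    of N mg", "dose range of N–M mg", "N–M times daily", dosage forms and
    routes.  Unmatched text yields an empty dict; callers keep the raw
    string instead of dropping the record.
    """
    out: Dict[str, str] = {}
    for key, pat in _DOSE_PATTERNS:
        m = pat.search(text)
        if m and key not in out:
            out[key] = m.group(1).strip()
    return out


def _concept_group(category: str, schema=None) -> str:
    if schema is not None:
        ct = schema.resolve_concept(category)
        if ct is not None:
            return _group(ct.name)
    return _group(category)


def mk_mst(graph: PropertyGraph, root: str, schema=None) -> SpanningTreeResult:
    """Minimum spanning tree of the root's component under cost 1/weight,
    with deterministic lexicographic tie-breaking, plus extraction of core
    medication attributes (dose, frequency, form, route, adverse reactions)
    from tree nodes whose concept is drug-application-like."""
    root_node = graph.find_node(root)
    component = set(_bfs_dist(graph, [root_node.node_id]))

    def edge_key(e: EdgeRecord):
        a = _sort_key(graph, e.start_node)
        b = _sort_key(graph, e.end_node)
        lo, hi = (a, b) if a <= b else (b, a)
        return (1.0 / e.weight, lo, hi, e.label, e.edge_id)

    parent = {n: n for n in component}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree_edges: List[EdgeRecord] = []
    for e in sorted((e for e in graph.edges()
                     if e.start_node in component and e.end_node in component),
                    key=edge_key):
        ru, rv = find(e.start_node), find(e.end_node)
        if ru != rv:
            parent[ru] = rv
            tree_edges.append(e)

    adj: Dict[int, List[int]] = {n: [] for n in component}
    for e in tree_edges:
        adj[e.start_node].append(e.end_node)
        adj[e.end_node].append(e.start_node)

    records: Dict[str, Dict[str, object]] = {}
    adverse: Set[str] = set()
    general: Dict[str, object] = {}

    def absorb(target: Dict[str, object], text: str) -> None:
        fields = parse_dosage(text)
        if fields:
            for k, v in fields.items():
                target.setdefault(k, v)
        else:
            target.setdefault("notes", [])
            target["notes"].append(text)  # keep raw string, never drop

    rid = root_node.node_id
    for nb in sorted(adj[rid], key=lambda n: _sort_key(graph, n)):
        node = graph.node(nb)
        concept = _concept_group(node.category, schema)
        if _in(node.category, DISEASE_LIKE | SYMPTOM_LIKE):
            record: Dict[str, object] = {}
            for nb2 in sorted(adj[nb], key=lambda n: _sort_key(graph, n)):
                if nb2 == rid:
                    continue
                inner = graph.node(nb2)
                if _concept_group(inner.category, schema) in _EXTRACT_CONCEPTS:
                    absorb(record, inner.name)
            records[node.name] = record
        elif concept == _group("adverse reactions"):
            adverse.add(node.name)
        elif concept in _EXTRACT_CONCEPTS:
            absorb(general, node.name)

    for key in ("form", "route"):
        if key in general:
            for record in records.values():
                record.setdefault(key, general[key])

    total_cost = sum(1.0 / e.weight for e in tree_edges)
    return SpanningTreeResult((root_node.name, root_node.category),
                              tree_edges, records, adverse, general, total_cost)


# ---------------------------------------------------------------------------
# 5. symptom intersection (CMIS)


def symptom_intersection(graph: PropertyGraph, symptoms: Sequence[str],
                         max_hops: int = DEFAULT_MAX_HOPS) -> IntersectionResult:
    """Nodes reachable from *every* query symptom within the hop bound,
    traversing only disease/symptom/drug/treatment-method nodes; shared
    drug-like or treatment-like nodes are reported as unified treatments."""
    if len(symptoms) < 2:
        raise ValueError("at least two query symptoms are required")
    traversal = DISEASE_LIKE | SYMPTOM_LIKE | DRUG_LIKE | TREATMENT_LIKE
    allowed = lambda nid: _in(graph.node(nid).category, traversal)
    seed_ids = [graph.find_node(s).node_id for s in symptoms]

    reach = [
        set(_bfs_dist(graph, [sid], max_hops, allowed)) for sid in seed_ids
    ]
    shared_ids = set.intersection(*reach) - set(seed_ids)

    shared: Dict[str, Dict[str, PathResult]] = {}
    unified: List[str] = []
    for nid in sorted(shared_ids, key=lambda n: _sort_key(graph, n)):
        node = graph.node(nid)
        links = {}
        for s, sid in zip(symptoms, seed_ids):
            ids = _lex_shortest_ids(graph, sid, nid, max_hops, allowed)
            links[s] = _path_result(graph, ids)
        shared[node.name] = links
        if _in(node.category, DRUG_LIKE | TREATMENT_LIKE):
            unified.append(node.name)
    return IntersectionResult(list(symptoms), shared, unified)


# ---------------------------------------------------------------------------
# 6. comorbidity shortest paths (CMC)


def comorbidity_shortest_paths(graph: PropertyGraph,
                               names: Optional[Sequence[str]] = None,
                               label_filter: Optional[Iterable[str]] = None,
                               max_hops: int = DEFAULT_MAX_HOPS
                               ) -> ComorbidityResult:
    """One minimum-hop undirected path per unordered pair of selected nodes.

    Nodes are selected by name and/or by category filter.  The path for each
    pair is the lexicographically smallest node-name sequence among the
    minimum-hop paths, oriented from the lexicographically smaller endpoint;
    duplicate paths are removed and unreachable pairs are counted, not
    errors.
    """
    selected: Set[int] = set()
    if names:
        for name in names:
            hits = [n.node_id for n in graph.nodes() if canon(n.name) == canon(name)]
            if not hits:
                raise NodeNotFoundError(f"no node named {name!r}")
            selected.update(hits)
    if label_filter is not None:
        groups = {_group(c) for c in label_filter}
        selected.update(n.node_id for n in graph.nodes()
                        if _group(n.category) in groups)
    if not selected:
        raise ValueError("no nodes selected")

    ordered = sorted(selected, key=lambda n: _sort_key(graph, n))
    paths: List[PathResult] = []
    seen: Set[tuple] = set()
    unreachable = 0
    for i, u in enumerate(ordered):
        for v in ordered[i + 1:]:
            ids = _lex_shortest_ids(graph, u, v, max_hops)
            if ids is None:
                unreachable += 1
                continue
            path = _path_result(graph, ids)
            sig = tuple(path.node_names())
            if sig not in seen:
                seen.add(sig)
                paths.append(path)
    return ComorbidityResult(paths, unreachable)


# ---------------------------------------------------------------------------
# 7. staged retrieval (CMDS)


def staged_retrieval(graph: PropertyGraph, stage_names: Sequence[str],
                     max_hops: int = DEFAULT_MAX_HOPS) -> StagedRetrievalResult:
    """Stages ordered topologically along their Stage edges (Kahn's
    algorithm, lexicographic tie-break), each with its directly attached
    treatment-method / drug / result neighbors, plus the shortest
    inter-stage paths."""
    stage_ids = [graph.find_node(s).node_id for s in stage_names]
    stage_set = set(stage_ids)

    succ: Dict[int, List[int]] = {n: [] for n in stage_ids}
    indeg: Dict[int, int] = {n: 0 for n in stage_ids}
    for e in graph.edges():
        if (canon(e.label) == "stage" and e.start_node in stage_set
                and e.end_node in stage_set and e.start_node != e.end_node):
            succ[e.start_node].append(e.end_node)
            indeg[e.end_node] += 1

    heap = [(_sort_key(graph, n), n) for n in stage_ids if indeg[n] == 0]
    heapq.heapify(heap)
    order: List[int] = []
    while heap:
        _, u = heapq.heappop(heap)
        order.append(u)
        for v in succ[u]:
            indeg[v] -= 1
            if indeg[v] == 0:
                heapq.heappush(heap, (_sort_key(graph, v), v))
    if len(order) != len(stage_ids):
        cycle = sorted(graph.node(n).name for n in stage_ids if n not in order)
        raise StageCycleError(cycle)

    reports = []
    for sid in order:
        treatments, drugs, results = [], [], []
        seen: Set[int] = set()
        for other, _e in graph.neighbors(sid):
            if other in stage_set or other in seen:
                continue
            seen.add(other)
            node = graph.node(other)
            if _in(node.category, TREATMENT_LIKE):
                treatments.append(node.name)
            elif _in(node.category, DRUG_LIKE):
                drugs.append(node.name)
            elif _in(node.category, RESULT_LIKE):
                results.append(node.name)
        reports.append(StageReport(graph.node(sid).name, sorted(treatments),
                                   sorted(drugs), sorted(results)))

    inter = comorbidity_shortest_paths(
        graph, names=[graph.node(s).name for s in stage_ids], max_hops=max_hops
    )
    return StagedRetrievalResult(reports, inter.paths)
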