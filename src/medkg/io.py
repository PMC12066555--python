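"""Interchange formats: quintuple TSV tables, graph JSON, GraphML, and
openCypher script export.

The quintuple table layout mirrors an entity-relation capture form:
``Entity1, Type1, Attribute1, Entity2, Type2, Attribute2, Direction,
R_name, R_label``.  ``Direction`` is ``forward`` or ``reverse``; reverse
rows are flipped into canonical forward quintuples at read time.  Attribute
cells hold ``key=value;key=value`` pairs.  All files are UTF-8 TSV without
BOM — drug descriptions contain commas, so TSV over CSV.

The Cypher exporter emits MERGE (never CREATE) statements so re-running a
script cannot duplicate knowledge: one MERGE per node keyed on
(name, category), one per edge keyed on endpoints and label, nodes before
edges, each block lexicographically sorted for byte-identical output.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple, Union

from .kg_core import PropertyGraph, Quintuple

__all__ = [
    "FIG9_COLUMNS",
    "FormatError",
    "CypherScript",
    "read_quintuple_table",
    "write_quintuple_table",
    "graph_to_json",
    "graph_from_json",
    "write_graph_json",
    "read_graph_json",
    "write_graphml",
    "export_cypher",
    "write_cypher",
]

FIG9_COLUMNS = [
    "Entity1", "Type1", "Attribute1", "Entity2", "Type2", "Attribute2",
    "Direction", "R_name", "R_label",
]
_MANDATORY = ["Entity1", "Type1", "Entity2", "Type2", "Direction", "R_name"]


class FormatError(ValueError):
    pass


def _parse_attrs(cell: str) -> Dict[str, str]:
    out: Dict[str, str] = {}
    for part in (cell or "").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"attribute cell entry without '=': {part!r}")
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _format_attrs(attrs: Dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in sorted(attrs.items()))


def read_quintuple_table(path: Union[str, Path]
                         ) -> Tuple[List[Quintuple], List[Tuple[int, str]]]:
    """Read a quintuple TSV; returns (quintuples, diagnostics).

    Malformed rows are collected as (line number, message) pairs and
    excluded, never silently skipped.  A missing mandatory column raises
    :class:`FormatError` naming the column.
    """
    rows: List[Quintuple] = []
    diagnostics: List[Tuple[int, str]] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file")
        col = {name: i for i, name in enumerate(header)}
        for name in _MANDATORY:
            if name not in col:
                raise FormatError(f"{path}: missing mandatory column {name!r}")

        def cell(row, name):
            i = col.get(name)
            return row[i].strip() if i is not None and i < len(row) else ""

        for line_no, row in enumerate(reader, start=2):
            if not any(c.strip() for c in row):
                continue
            missing = [n for n in _MANDATORY if not cell(row, n)]
            if missing:
                diagnostics.append(
                    (line_no, f"empty mandatory field(s): {', '.join(missing)}")
                )
                continue
            direction = cell(row, "Direction").lower()
            if direction not in {"forward", "reverse"}:
                diagnostics.append(
                    (line_no, f"invalid Direction {cell(row, 'Direction')!r}")
                )
                continue
            try:
                a1 = _parse_attrs(cell(row, "Attribute1"))
                a2 = _parse_attrs(cell(row, "Attribute2"))
            except ValueError as exc:
                diagnostics.append((line_no, str(exc)))
                continue
            sub, sub_t, sub_a = cell(row, "Entity1"), cell(row, "Type1"), a1
            obj, obj_t, obj_a = cell(row, "Entity2"), cell(row, "Type2"), a2
            if direction == "reverse":
                sub, sub_t, sub_a, obj, obj_t, obj_a = (
                    obj, obj_t, obj_a, sub, sub_t, sub_a)
            rows.append(
                Quintuple(sub, sub_t, cell(row, "R_name"), obj, obj_t,
                          sub_attrs=sub_a, obj_attrs=obj_a,
                          rel_label=cell(row, "R_label"))
            )
    return rows, diagnostics


def write_quintuple_table(rows: List[Quintuple], path: Union[str, Path]) -> None:
    """Write quintuples in canonical forward orientation."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FIG9_COLUMNS)
        for q in rows:
            writer.writerow([
                q.sub, q.sub_type, _format_attrs(q.sub_attrs),
                q.obj, q.obj_type, _format_attrs(q.obj_attrs),
                "forward", q.rel, q.rel_label or q.rel,
            ])


# ---------------------------------------------------------------------------
# graph JSON / GraphML


def graph_to_json(graph: PropertyGraph) -> dict:
    return {
        "nodes": [
            {
                "id": n.node_id,
                "name": n.name,
                "category": n.category,
                "attributes": dict(n.attributes),
            }
            for n in graph.nodes()
        ],
        "edges": [
            {
                "start": e.start_node,
                "end": e.end_node,
                "label": e.label,
                "weight": e.weight,
                "attributes": dict(e.attributes),
            }
            for e in graph.edges()
        ],
    }


def graph_from_json(doc: dict) -> PropertyGraph:
    graph = PropertyGraph()
    id_map = {}
    for n in doc["nodes"]:
        id_map[n["id"]] = graph.add_node(n["name"], n["category"],
                                         dict(n.get("attributes", {})))
    for e in doc["edges"]:
        graph.add_edge(id_map[e["start"]], e["label"], id_map[e["end"]],
                       weight=int(e.get("weight", 1)),
                       attributes=dict(e.get("attributes", {})))
    return graph


def write_graph_json(graph: PropertyGraph, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(graph_to_json(graph), fh, ensure_ascii=False, indent=1)
        fh.write("\n")


def read_graph_json(path: Union[str, Path]) -> PropertyGraph:
    with open(path, encoding="utf-8") as fh:
        return graph_from_json(json.load(fh))


def write_graphml(graph: PropertyGraph, path: Union[str, Path]) -> None:
    import networkx as nx

    nx.write_graphml(graph.to_networkx(), str(path))


# ---------------------------------------------------------------------------
# Cypher export


@dataclass
class CypherScript:
    statements: List[str] = field(default_factory=list)
    statistics: Dict[str, int] = field(default_factory=dict)

    def text(self) -> str:
        return "\n".join(self.statements) + ("\n" if self.statements else "")


def _esc(value: str) -> str:
    return value.replace("\\", "\\\\").replace("'", "\\'")


def _label(value: str) -> str:
    return "`" + value.replace("`", "``") + "`"


def _props(attrs: Dict[str, str]) -> str:
    return ", ".join(f"{_label(k)}: '{_esc(str(v))}'"
                     for k, v in sorted(attrs.items()))


def export_cypher(graph: PropertyGraph) -> CypherScript:
    """Deterministic openCypher script: all node MERGEs, then all edge
    MERGEs, each block sorted; weight and attributes carried as properties."""
    node_stmts = []
    for n in graph.nodes():
        stmt = (f"MERGE (n:{_label(n.category)} {{name: '{_esc(n.name)}'}})")
        if n.attributes:
            stmt += f" SET n += {{{_props(n.attributes)}}}"
        stmt += ";"
        node_stmts.append(stmt)
    edge_stmts = []
    for e in graph.edges():
        s, t = graph.node(e.start_node), graph.node(e.end_node)
        stmt = (
            f"MATCH (a:{_label(s.category)} {{name: '{_esc(s.name)}'}}), "
            f"(b:{_label(t.category)} {{name: '{_esc(t.name)}'}}) "
            f"MERGE (a)-[r:{_label(e.label)}]->(b) "
            f"SET r.weight = {e.weight}"
        )
        if e.attributes:
            stmt += f", r += {{{_props(e.attributes)}}}"
        stmt += ";"
        edge_stmts.append(stmt)
    statements = sorted(node_stmts) + sorted(edge_stmts)
    return CypherScript(
        statements,
        {"n_merge_node": len(node_stmts), "n_merge_edge": len(edge_stmts)},
    )


def write_cypher(graph: PropertyGraph, path: Union[str, Path]) -> CypherScript:
    script = export_cypher(graph)
    Path(path).write_text(script.text(), encoding="utf-8")
    return script
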