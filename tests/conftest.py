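import itertools

import numpy as np
import pytest

from medkg.kg_core import PropertyGraph, Quintuple, ingest_quintuples
from medkg.fixtures import SECTIONS, load_section_rows
from medkg.ontology import packaged_schema

CATEGORIES = ["Drugs", "Diseases", "Symptoms", "Treatment methods",
              "Drug combinations", "Indications"]


@pytest.fixture(scope="session")
def schema():
    return packaged_schema()


@pytest.fixture(scope="session")
def section_rows():
    return {name: load_section_rows(name) for name in SECTIONS}


@pytest.fixture(scope="session")
def section_graphs(section_rows):
    return {name: ingest_quintuples(rows) for name, rows in section_rows.items()}


def random_quintuples(rng: np.random.Generator, n_nodes: int, n_rows: int,
                      max_weight: int = 4):
    """Random quintuple rows over a small node pool; duplicates realize
    weights > 1."""
    names = [f"n{i}" for i in range(n_nodes)]
    cats = {name: CATEGORIES[int(rng.integers(len(CATEGORIES)))]
            for name in names}
    rows = []
    for _ in range(n_rows):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        sub, obj = names[int(a)], names[int(b)]
        rel = f"rel{int(rng.integers(3))}"
        for _ in range(int(rng.integers(1, max_weight + 1))):
            rows.append(Quintuple(sub, cats[sub], rel, obj, cats[obj]))
    return rows


def random_graph(rng: np.random.Generator, n_nodes: int, n_rows: int,
                 max_weight: int = 4) -> PropertyGraph:
    return ingest_quintuples(random_quintuples(rng, n_nodes, n_rows, max_weight))


def connected_random_graph(rng: np.random.Generator, n_nodes: int,
                           n_extra: int, max_weight: int = 4) -> PropertyGraph:
    """Random spanning chain plus extra edges: always connected."""
    names = [f"n{i}" for i in range(n_nodes)]
    graph = PropertyGraph()
    ids = [graph.add_node(n, CATEGORIES[int(rng.integers(len(CATEGORIES)))])
           for n in names]
    order = rng.permutation(n_nodes)
    for a, b in zip(order, order[1:]):
        graph.add_edge(ids[int(a)], f"rel{int(rng.integers(3))}", ids[int(b)],
                       weight=int(rng.integers(1, max_weight + 1)))
    for _ in range(n_extra):
        a, b = rng.choice(n_nodes, size=2, replace=False)
        graph.add_edge(ids[int(a)], f"rel{int(rng.integers(3))}", ids[int(b)],
                       weight=int(rng.integers(1, max_weight + 1)))
    return graph


def enumerate_spanning_trees(graph: PropertyGraph):
    """All spanning trees of a (connected) graph, as edge-record tuples.
    Exhaustive: only usable for tiny graphs."""
    nodes = [n.node_id for n in graph.nodes()]
    edges = graph.edges()
    k = len(nodes) - 1
    for combo in itertools.combinations(edges, k):
        parent = {n: n for n in nodes}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        acyclic = True
        for e in combo:
            ru, rv = find(e.start_node), find(e.end_node)
            if ru == rv:
                acyclic = False
                break
            parent[ru] = rv
        if acyclic:
            yield combo
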