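"""Reasoning procedures checked against exhaustive / reimplemented oracles
on small random graphs, plus the packaged beta-blocker case studies."""

import networkx as nx
import numpy as np
import pytest

from medkg.kg_core import Quintuple, ingest_quintuples
from medkg.reason import (
    CategoryError,
    StageCycleError,
    comorbidity_shortest_paths,
    connectivity_subgraph,
    mk_mst,
    multi_use_discovery,
    staged_retrieval,
    symptom_intersection,
    synergy_critical_path,
)

from conftest import connected_random_graph, enumerate_spanning_trees, random_graph


def undirected_view(graph):
    g = nx.Graph()
    for n in graph.nodes():
        g.add_node(n.node_id)
    for e in graph.edges():
        g.add_edge(e.start_node, e.end_node)
    return g


def assert_provenance(graph, path):
    """Every reported path edge must exist in the source graph with the
    same label and weight."""
    for pe in path.edges:
        edge = graph.find_edge(pe.start, pe.label, pe.end)
        assert edge.weight == pe.weight


class TestConnectivitySubgraph:
    def test_zero_hops_seeds_only(self, section_graphs):
        g = section_graphs["multi_use"]
        sub = connectivity_subgraph(g, ["beta-blockers"], max_hops=0)
        assert [n.name for n in sub.nodes()] == ["beta-blockers"]
        assert sub.edges() == []

    def test_star_graph_one_hop(self):
        rows = [Quintuple("hub", "Drugs", "r", f"leaf{i}", "Diseases")
                for i in range(5)]
        g = ingest_quintuples(rows)
        sub = connectivity_subgraph(g, ["hub"], max_hops=1)
        assert len(sub.nodes()) == 6 and len(sub.edges()) == 5

    @pytest.mark.parametrize("seed", range(60))
    def test_matches_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = random_graph(rng, 8, 12)
        seed_node = g.nodes()[int(rng.integers(len(g.nodes())))]
        hops = int(rng.integers(0, 4))
        sub = connectivity_subgraph(g, [seed_node.name], max_hops=hops)
        lengths = nx.single_source_shortest_path_length(
            undirected_view(g), seed_node.node_id, cutoff=hops)
        expected = {(g.node(n).name, g.node(n).category) for n in lengths}
        assert {(n.name, n.category) for n in sub.nodes()} == expected


class TestMultiUse:
    def test_beta_blocker_indications(self, section_graphs):
        result = multi_use_discovery(section_graphs["multi_use"],
                                     "beta-blockers", max_hops=2)
        assert set(result) == {"heart failure", "hypertension",
                               "hereditary long QT", "congestive heart failure"}
        for paths in result.values():
            for p in paths:
                assert_provenance(section_graphs["multi_use"], p)

    def test_two_hop_indication_needs_two_hops(self):
        rows = [
            Quintuple("drugX", "Drugs", "AT", "X-Indications", "Indications"),
            Quintuple("X-Indications", "Indications", "Indications",
                      "diseaseY", "Diseases"),
        ]
        g = ingest_quintuples(rows)
        assert multi_use_discovery(g, "drugX", max_hops=1) == {}
        two = multi_use_discovery(g, "drugX", max_hops=2)
        assert set(two) == {"diseaseY"}
        assert two["diseaseY"][0].hops == 2

    def test_no_disease_connections_empty(self):
        g = ingest_quintuples(
            [Quintuple("drugX", "Drugs", "Properties", "tablet form",
                       "Drug applications")])
        assert multi_use_discovery(g, "drugX", max_hops=3) == {}

    def test_non_drug_rejected(self, section_graphs):
        with pytest.raises(CategoryError):
            multi_use_discovery(section_graphs["multi_use"], "heart failure")

    @pytest.mark.parametrize("seed", range(40))
    def test_monotone_in_hops_and_shortest(self, seed):
        rng = np.random.default_rng(seed + 99)
        g = random_graph(rng, 8, 12)
        drugs = [n for n in g.nodes() if n.category == "Drugs"]
        if not drugs:
            pytest.skip("no drug node drawn")
        drug = drugs[0]
        view = undirected_view(g)
        prev_keys = set()
        for hops in range(0, 4):
            result = multi_use_discovery(g, drug.name, max_hops=hops)
            assert prev_keys <= set(result)
            prev_keys = set(result)
            dist = nx.single_source_shortest_path_length(
                view, drug.node_id, cutoff=hops)
            for name, paths in result.items():
                node = g.find_node(name)
                assert paths[0].hops == dist[node.node_id]
                assert_provenance(g, paths[0])


class TestSynergy:
    def test_congestive_heart_failure_combination(self, section_graphs):
        entries = synergy_critical_path(section_graphs["synergy"],
                                        "congestive heart failure")
        assert entries
        top = entries[0]
        assert {"metoprolol", "bisoprolol", "carvedilol",
                "felodipine"} <= set(top.drug_set)
        assert_provenance(section_graphs["synergy"], top.path)

    def test_single_edge_critical_path(self):
        g = ingest_quintuples(
            [Quintuple("drugX", "Drugs", "Treatment", "diseaseY", "Diseases")] * 2)
        entries = synergy_critical_path(g, "diseaseY")
        assert len(entries) == 1
        assert entries[0].total_weight == 2
        assert entries[0].path.hops == 1

    def test_isolated_disease_empty(self):
        g = ingest_quintuples(
            [Quintuple("a", "Drugs", "r", "b", "Diseases")])
        g.add_node("lonely disease", "Diseases")
        assert synergy_critical_path(g, "lonely disease") == []

    @pytest.mark.parametrize("seed", range(60))
    def test_path_weight_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed + 7)
        g = random_graph(rng, 8, 11)
        diseases = [n for n in g.nodes() if n.category == "Diseases"]
        if not diseases:
            pytest.skip("no disease node drawn")
        disease = diseases[0]
        entries = synergy_critical_path(g, disease.name, max_hops=6)

        # oracle: rebuild the layered DAG independently and enumerate every
        # simple path from the seed by DFS, keeping the max weight per target
        view = undirected_view(g)
        layer = nx.single_source_shortest_path_length(view, disease.node_id,
                                                      cutoff=6)
        dag = nx.DiGraph()
        dag.add_nodes_from(layer)
        for e in g.edges():
            if e.start_node in layer and e.end_node in layer:
                u, v = e.start_node, e.end_node
                if layer[u] + 1 == layer[v]:
                    pass
                elif layer[v] + 1 == layer[u]:
                    u, v = v, u
                else:
                    continue
                # parallel stored edges: the heaviest one wins the DAG arc
                w = max(e.weight, dag.edges[u, v]["weight"]) \
                    if dag.has_edge(u, v) else e.weight
                dag.add_edge(u, v, weight=w)
        best = {}
        stack = [(disease.node_id, 0)]
        while stack:
            node, w = stack.pop()
            if w > best.get(node, -1):
                best[node] = w
            for _u, v, data in dag.out_edges(node, data=True):
                stack.append((v, w + data["weight"]))
        for entry in entries:
            nid = g.find_node(entry.target[0], entry.target[1]).node_id
            assert entry.total_weight == best[nid]
            assert_provenance(g, entry.path)


class TestMkMst:
    def test_propranolol_dosing_extraction(self, section_graphs, schema):
        result = mk_mst(section_graphs["mst"], "propranolol", schema=schema)
        hyp = result.records["hypertension"]
        assert hyp["initial_dose"] == "10 mg"
        assert hyp["max_dose"] == "200 mg"
        assert hyp["frequency"] == "3–4 times daily"
        assert hyp["form"] == "tablet"
        mi = result.records["myocardial infarction"]
        assert mi["dose_range"] == "30–240 mg"
        assert mi["frequency"] == "2–3 times daily"
        assert result.adverse_reactions == {
            "sinus bradycardia", "atrioventricular block", "hypotension"}

    def test_tree_edge_count(self, section_graphs):
        for g in section_graphs.values():
            root = g.nodes()[0]
            result = mk_mst(g, root.name, )
            component = nx.node_connected_component(undirected_view(g),
                                                    root.node_id)
            assert len(result.edges) == len(component) - 1

    def test_unparsed_attribute_kept_as_note(self):
        rows = [
            Quintuple("drugZ", "Drugs", "Indications", "diseaseQ", "Diseases"),
            Quintuple("diseaseQ", "Diseases", "Properties",
                      "take with food", "Drug applications"),
        ]
        g = ingest_quintuples(rows)
        result = mk_mst(g, "drugZ")
        assert result.records["diseaseQ"]["notes"] == ["take with food"]

    def test_missing_root(self, section_graphs):
        from medkg.kg_core import NodeNotFoundError

        with pytest.raises(NodeNotFoundError):
            mk_mst(section_graphs["mst"], "no such drug")

    @pytest.mark.parametrize("seed", range(50))
    def test_cost_matches_spanning_tree_enumeration(self, seed):
        rng = np.random.default_rng(seed + 13)
        g = connected_random_graph(rng, n_nodes=int(rng.integers(3, 7)),
                                   n_extra=int(rng.integers(0, 4)))
        root = g.nodes()[0]
        result = mk_mst(g, root.name, )
        best = min(
            sum(1.0 / e.weight for e in tree)
            for tree in enumerate_spanning_trees(g)
        )
        assert result.total_cost == pytest.approx(best)
        for e in result.edges:
            assert g.edge(e.edge_id) is e  # provenance: edges of the source


class TestSymptomIntersection:
    def test_bradycardia_shared(self, section_graphs):
        res = symptom_intersection(
            section_graphs["intersection"],
            ["atrial fibrillation", "sinus bradycardia"], max_hops=2)
        assert "bradycardia" in res.shared_nodes
        assert res.unified_treatments == ["β-receptor blockers"]
        for links in res.shared.values():
            for p in links.values():
                assert_provenance(section_graphs["intersection"], p)

    def test_disjoint_components_empty(self):
        rows = [Quintuple("s1", "Symptoms", "Shows", "a", "Symptoms"),
                Quintuple("s2", "Symptoms", "Shows", "b", "Symptoms")]
        g = ingest_quintuples(rows)
        res = symptom_intersection(g, ["s1", "s2"], max_hops=4)
        assert res.shared == {} and res.unified_treatments == []

    def test_needs_two_symptoms(self, section_graphs):
        with pytest.raises(ValueError):
            symptom_intersection(section_graphs["intersection"],
                                 ["bradycardia"])

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_per_seed_bfs_intersection_oracle(self, seed):
        rng = np.random.default_rng(seed + 31)
        g = random_graph(rng, 8, 12)
        symptoms = [n for n in g.nodes() if n.category == "Symptoms"]
        if len(symptoms) < 2:
            pytest.skip("need two symptom nodes")
        a, b = symptoms[0], symptoms[1]
        hops = int(rng.integers(1, 4))
        res = symptom_intersection(g, [a.name, b.name], max_hops=hops)

        allowed_cats = {"Drugs", "Diseases", "Symptoms", "Treatment methods",
                        "Drug combinations"}
        view = nx.Graph()
        for n in g.nodes():
            view.add_node(n.node_id)
        for e in g.edges():
            view.add_edge(e.start_node, e.end_node)

        def reach(seed_id):
            out = {seed_id: 0}
            frontier = [seed_id]
            for d in range(hops):
                nxt = []
                for u in frontier:
                    for v in view.neighbors(u):
                        if v not in out and g.node(v).category in allowed_cats:
                            out[v] = d + 1
                            nxt.append(v)
                frontier = nxt
            return set(out)

        expected = (reach(a.node_id) & reach(b.node_id)) - {a.node_id, b.node_id}
        assert set(res.shared_nodes) == {g.node(n).name for n in expected}


class TestComorbidity:
    def test_fixture_paths(self, section_graphs):
        g = section_graphs["comorbidity"]
        res = comorbidity_shortest_paths(
            g, names=["hypertension", "intravenous beta-blockers",
                      "hypertension combined with diabetes", "beta-blockers"])
        by_ends = {frozenset({p.node_names()[0], p.node_names()[-1]}): p
                   for p in res.paths}
        treat = by_ends[frozenset({"hypertension", "intravenous beta-blockers"})]
        assert [e.label for e in treat.edges] == ["Treatment"]
        contra = by_ends[frozenset({"hypertension combined with diabetes",
                                    "beta-blockers"})]
        assert [e.label for e in contra.edges] == ["Contraindications"]

    def test_adjacent_nodes_one_hop(self):
        g = ingest_quintuples(
            [Quintuple("a", "Drugs", "Treatment", "b", "Diseases")])
        res = comorbidity_shortest_paths(g, names=["a", "b"])
        assert len(res.paths) == 1 and res.paths[0].hops == 1

    def test_unreachable_counted_not_raised(self):
        rows = [Quintuple("a", "Drugs", "r", "b", "Diseases"),
                Quintuple("c", "Drugs", "r", "d", "Diseases")]
        g = ingest_quintuples(rows)
        res = comorbidity_shortest_paths(g, names=["a", "c"])
        assert res.paths == [] and res.n_unreachable == 1

    @pytest.mark.parametrize("seed", range(60))
    def test_lengths_match_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed + 77)
        g = random_graph(rng, 8, 12)
        if not any(n.category in {"Drugs", "Diseases"} for n in g.nodes()):
            pytest.skip("no drug/disease node drawn")
        res = comorbidity_shortest_paths(g, label_filter=["Drugs", "Diseases"],
                                         max_hops=6)
        view = undirected_view(g)
        for p in res.paths:
            src = g.find_node(p.node_names()[0], p.nodes[0][1]).node_id
            dst = g.find_node(p.node_names()[-1], p.nodes[-1][1]).node_id
            assert p.hops == nx.shortest_path_length(view, src, dst)
            assert_provenance(g, p)
            names = p.node_names()
            assert len(set(names)) == len(names)  # simple path


class TestStagedRetrieval:
    def test_hypertension_grades(self, section_graphs):
        res = staged_retrieval(
            section_graphs["stages"],
            ["grade I hypertension", "grade II hypertension",
             "grade III hypertension"])
        order = [r.stage for r in res.order]
        assert order == ["grade I hypertension", "grade II hypertension",
                         "grade III hypertension"]
        grade1 = res.order[0]
        assert set(grade1.treatment_methods) == {
            "lifestyle interventions",
            "ARNI or diuretic monotherapy after 4–12 weeks"}
        grade2 = res.order[1]
        assert "ARNI or diuretic monotherapy" in grade2.treatment_methods
        assert "ARNI" in grade2.drugs
        assert "target organ damage risk" in res.order[2].results

    def test_single_stage_singleton(self):
        g = ingest_quintuples(
            [Quintuple("only stage", "Diseases", "Treatment",
                       "rest", "Treatment methods")])
        res = staged_retrieval(g, ["only stage"])
        assert [r.stage for r in res.order] == ["only stage"]

    def test_cycle_raises_with_members(self):
        rows = [Quintuple("s1", "Diseases", "Stage", "s2", "Diseases"),
                Quintuple("s2", "Diseases", "Stage", "s1", "Diseases")]
        g = ingest_quintuples(rows)
        with pytest.raises(StageCycleError) as exc:
            staged_retrieval(g, ["s1", "s2"])
        assert set(exc.value.cycle) == {"s1", "s2"}

    @pytest.mark.parametrize("seed", range(40))
    def test_order_respects_every_stage_edge(self, seed):
        rng = np.random.default_rng(seed + 55)
        n = int(rng.integers(3, 7))
        names = [f"stage{i}" for i in range(n)]
        rows = []
        perm = list(rng.permutation(n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.4:
                    rows.append(Quintuple(names[perm[i]], "Diseases", "Stage",
                                          names[perm[j]], "Diseases"))
        if not rows:
            rows.append(Quintuple(names[0], "Diseases", "Stage",
                                  names[1], "Diseases"))
        g = ingest_quintuples(rows)
        present = sorted({q.sub for q in rows} | {q.obj for q in rows})
        res = staged_retrieval(g, present)
        position = {r.stage: i for i, r in enumerate(res.order)}
        for q in rows:
            assert position[q.sub] < position[q.obj]


class TestReadOnly:
    def test_operations_leave_graph_unchanged(self, section_graphs, schema):
        for name, g in section_graphs.items():
            before = g.canonical_form()
            if name == "multi_use":
                multi_use_discovery(g, "beta-blockers", max_hops=3)
            elif name == "synergy":
                synergy_critical_path(g, "congestive heart failure")
            elif name == "mst":
                mk_mst(g, "propranolol", schema=schema)
            elif name == "intersection":
                symptom_intersection(
                    g, ["atrial fibrillation", "sinus bradycardia"])
            elif name == "comorbidity":
                comorbidity_shortest_paths(g, names=["hypertension"],
                                           label_filter=["Drugs"])
            else:
                staged_retrieval(g, ["grade I hypertension",
                                     "grade II hypertension"])
            assert g.canonical_form() == before
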