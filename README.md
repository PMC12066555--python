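# medkg

Quintuple-based medication knowledge graphs with frequency-weighted
relations, ontology-schema validation, and graph reasoning for
drug–disease–symptom networks.

Clinical medication knowledge — which drug class treats which disease, at
what dose, in which disease stage, and with which contraindications — is
scattered across guidelines and expert consensus as prose. `medkg` models
that knowledge as **quintuples**

```
Y = (SUB, SUBT, R, OBJ, OBJT)
```

— subject, subject category, relation, object, object category — where the
quintuple is *direction-asymmetric*: `(A, …, R, B, …) ≠ (B, …, R, A, …)`.
Quintuples are ingested into a labeled property graph in which re-asserting
a (subject, relation, object) triple increments the edge's **weight** (its
occurrence frequency), so heavily supported relationships stand out.  Edges
are stored as doubly linked edge records (per-node incidence lists with
previous/next pointers on both endpoints), the layout used by native graph
stores.

On top of the graph, the package provides six reasoning procedures:

| procedure | question it answers |
|---|---|
| `multi_use_discovery` | which diseases/symptoms does this drug reach ("one drug, multiple uses")? |
| `synergy_critical_path` | which drug combination has the heaviest critical path to this disease? |
| `mk_mst` | what are the core dosing facts for this drug (minimum spanning tree under cost 1/weight)? |
| `symptom_intersection` | which nodes are shared by several symptoms, and is there a unified treatment? |
| `comorbidity_shortest_paths` | how are comorbidities and their medications connected (all-pairs shortest paths)? |
| `staged_retrieval` | what is prescribed at each disease stage, in stage (topological) order? |

A typed ontology schema — medication types (MT), their attribute entries
(AMT), a 17-term concept vocabulary, a 17-relation vocabulary, and
advisory category-pair rules — validates every quintuple.  A seeded
synthetic generator plants recoverable patterns (indication chains, boosted
combinations, dosing trees, symptom intersections, stage chains) so every
procedure is testable without external data, and a Cypher exporter emits
idempotent `MERGE` scripts for a property-graph database.

## Worked example

The package ships small quintuple tables transcribing a beta-blocker case
study.  Extract propranolol's core dosing knowledge:

```python
from medkg.fixtures import load_beta_blocker_graph
from medkg.ontology import packaged_schema
from medkg.reason import mk_mst

graph = load_beta_blocker_graph(["mst"])
tree = mk_mst(graph, "propranolol", schema=packaged_schema())
print(tree.records)
print(sorted(tree.adverse_reactions))
```

prints

```
{'hypertension': {'frequency': '3–4 times daily', 'initial_dose': '10 mg',
                  'max_dose': '200 mg', 'form': 'tablet'},
 'myocardial infarction': {'frequency': '2–3 times daily',
                           'dose_range': '30–240 mg', 'form': 'tablet'}}
['atrioventricular block', 'hypotension', 'sinus bradycardia']
```

i.e. for hypertension, propranolol tablets start at 10 mg and may be
titrated to a 200 mg maximum taken 3–4 times daily; for myocardial
infarction the dose range is 30–240 mg, 2–3 times daily; watch for
bradycardia, AV block and hypotension.  The same graph answers multi-use
queries:

```python
from medkg.reason import multi_use_discovery
graph = load_beta_blocker_graph(["multi_use"])
print(sorted(multi_use_discovery(graph, "beta-blockers", max_hops=2)))
# ['congestive heart failure', 'heart failure', 'hereditary long QT', 'hypertension']
```

Everything is also reachable from the CLI:

```sh
medkg mst src/medkg/data/bb_343_mst.tsv --root propranolol
medkg reason multi-use src/medkg/data/bb_341_multi_use.tsv --drug beta-blockers --max-hops 2
medkg simulate --config cfg.yaml --seed 7 --out sim/
medkg export src/medkg/data/bb_342_synergy.tsv --out graph.cypher
```

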