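# Methods

## Data model

The atomic knowledge unit is the quintuple `(SUB, SUBT, R, OBJ, OBJT)`:
two named, categorized entities joined by a directed, labeled relation.
Quintuples are direction-asymmetric by definition; an undirected question
is answered by scanning both incidence sides of the stored directed edges,
never by storing a mirrored edge.

**Node identity is (name, category).** Clinical vocabularies reuse surface
names across categories (a term can name both a disease and a symptom;
"sinus bradycardia" appears both as an adverse reaction and as a symptom),
so name alone is not an identity. When an incoming row reuses a name under
a new category, the default policy *forks* a second node and logs a note;
a `reject` policy is available for curated pipelines that treat this as an
error.

**Edge weight = row-level support count.** Re-asserting an existing
(subject, relation, object) triple increments the stored edge's weight by
one. Whether support should be counted per sentence or per document is
genuinely open; row-level counting is the simplest auditable unit and is
what the ingestion conserves: the number of edges equals the number of
distinct triples, and the weight total equals the number of accepted rows.
`grade_weights` turns raw counts into 1-based quantile tiers over the
*distinct* weights (near-equal runs of the sorted distinct values), so
equal weights always share a tier and tier order follows weight order;
asking for more tiers than distinct weights collapses gracefully.

**Storage layout.** Nodes carry a pointer to their first incident edge;
each edge carries previous/next pointers for both its start-node list
(`sp`/`sn`) and its end-node list (`ep`/`en`). Scanning a node's incidence
list therefore touches only its own edges and returns them in insertion
order. The layout is an internal contract — the test suite checks it
against a full-scan filter on every generated graph — not a serialization
format; interchange goes through quintuple TSV, graph JSON, GraphML and
Cypher.

## Ontology schema

The schema is a typed vocabulary: a list of medication types (MT), their
attribute entries (AMT, each resolving to one of 17 concept terms), a
closed relation vocabulary (17 relation types), and a table of
category-pair rules recording which relations were observed between which
entity categories.

Matching is case-insensitive after Unicode NFC normalization, with an
alias table on concept terms absorbing singular/plural and editorial
variants ("Drug"/"Drugs", "Treatment methods"/"Therapeutic approaches")
and a final-s-insensitive comparison for category groups. The MT list is
configuration (taken from the AMT table when not supplied), not a
hard-coded constant.

Pair rules are *advisory by default*: the source table is an explicit
sample (most cells end in "etc."), so a missing pair or an unlisted
relation is a warning unless `strict=True`. Unknown categories and unknown
relations are always violations. Relations that appear only in the
pair-rule sample are accepted as known for validation but are reported on
`schema.unresolved` and excluded from the declared-relation count.

## Normalization

Standardization rules come in five kinds applied in a fixed order —
category unification, synonym unification, expression normalization,
reference filling (one term fans out into several, e.g. "intravenous X or
Y" → "intravenous X", "intravenous Y"), redundancy simplification. Rules
are whole-term, case-insensitive patterns; unmatched input passes through
unchanged, which makes the operation idempotent for rule sets whose
replacements are fixed points (the packaged set is).

Segmentation is greedy longest-match, left to right, against the
pharmacopoeia and disease codex: at each position the longest lexicon term
starting there becomes one token, so "acute myocardial infarction" never
fragments even when "myocardial infarction" is also in the codex. Length
ties break by lexicon priority (pharmacopoeia before codex before user
lexicons) — the overlap resolution is a documented choice, not forced by
the source material. Non-matching spans fall through to single CJK
characters, whitespace runs, or word runs; concatenating token texts
always reproduces the input exactly.

Alias merging resolves names through the lexicon alias maps (transitively,
so a→b and b→c both land on c) and merges only same-category nodes;
a cross-category collision on one canonical name is skipped and reported.
Re-attached parallel edges coalesce by weight addition, conserving total
edge weight.

## Reasoning procedures

All six procedures are read-only, and every path or tree edge they return
exists in the source graph with its stored label and weight.

* **Connectivity subgraph** — bounded undirected BFS from seed nodes,
  optionally restricted to a category set (seeds always included);
  the substrate for the other procedures.
* **Multi-use discovery** — disease/symptom nodes within `max_hops` of a
  drug-like node, each witnessed by a shortest simple path; results are
  ordered by (hops, descending path weight, name). Monotone in the hop
  bound.
* **Synergy critical path** — the disease's neighborhood is layered by BFS
  depth and turned into a DAG whose arcs run from shallower to deeper
  layers (intra-layer edges dropped; this DAG construction is an isolated
  function so alternatives can be swapped). A dynamic program computes the
  maximum-total-weight path to each target. Targets are drug-combination
  nodes; when none is reachable the ranking falls back to plain drug
  nodes, so a bare disease–drug edge is its own critical path. Restricting
  targets to combinations is deliberate: ranking arbitrary drug nodes lets
  long chains of weight-1 edges outrank a heavily supported combination,
  which defeats the purpose of weighting. An entry's drug set collects
  drug nodes on the path plus the members of any combination node on it.
* **MK-MST** — minimum spanning tree of the root's component under edge
  cost 1/weight. The weights encode relationship importance, so the
  "minimum" tree must *retain* high-frequency edges; inverse cost is the
  simplest scheme with that property. Kruskal with a total edge order
  (cost, sorted endpoint names, label, edge id) makes ties deterministic.
  Extraction then walks the tree from the root: disease/symptom neighbors
  become indication records, their application-concept neighbors are
  parsed for dosing fields, root-level application nodes contribute shared
  fields (dosage form, route), and adverse-reaction neighbors form the
  precaution set. Dose parsing uses one documented pattern family
  ("initial dose of N mg", "maximum dosage of N mg", "dose range of
  N–M mg", "N–M times daily", forms, routes); text that matches nothing is
  kept verbatim under `notes`, never dropped.
* **Symptom intersection** — per-symptom bounded BFS restricted to
  disease/symptom/drug/treatment-method categories; shared nodes are the
  intersection of the reachability sets (query symptoms excluded), each
  annotated with a shortest path from every query symptom; shared
  drug-like or treatment-like nodes are the unified treatments.
* **Comorbidity shortest paths** — one minimum-hop undirected path per
  unordered pair of selected nodes; hop-count semantics (the property-graph
  default), not weight-based. The reported path is the lexicographically
  smallest node-name sequence among the minimum-hop paths, oriented from
  the smaller endpoint; duplicates are removed and unreachable pairs
  counted rather than raised.
* **Staged retrieval** — Kahn's topological sort of the Stage-labeled
  edges among the query stages (lexicographic tie-break; a cycle raises an
  error listing its members), then per-stage direct neighbors bucketed
  into treatment methods, drugs and results, plus the inter-stage shortest
  paths.

Unbounded path searches take a default `max_hops=6` (configurable):
unbounded simple-path search is exponential and six hops already spans
drug → combination → member → disease → stage → treatment chains.

## Synthetic generator

The generator emulates the shape of guideline-derived medication graphs at
the quintuple level — MT/drug/disease/symptom/treatment categories and the
packaged relation vocabulary — not guideline text. Planted patterns carry
their expected answers as ground truth:

* `multi_use(drug, k, depth)` — k chains of the given depth ending in
  distinct diseases;
* `synergy(disease, drugs, boost)` — a combination node tied to the
  disease by a boost-weighted "combined effect" edge (boost default 3,
  realized by duplicate emission, matching the case-study support count);
* `dosage_tree(drug, indications, adverse)` — the dosing-subtree shape;
* `intersection(a, b, shared, treatment)` and `stage_chain(disease, n)`.

Background edges are drawn uniformly over schema-allowed category-pair
templates; the pools include planted entities, so noise genuinely competes
with the planted structure. A single integer seed drives one numpy
Generator; output is byte-identical for equal (seed, config), and
unsatisfiable patterns fail before any output. With zero background edges
every planted pattern is recovered exactly (hard assertion in the tests).

What the generator does **not** emulate: natural-language extraction noise,
category ambiguity, alias variation, or the size of a real guideline graph
(thousands of entities). Passing recovery tests therefore demonstrates the
correctness of the reasoning procedures on well-formed graphs, not
robustness to extraction error.

## Numerical and testing choices

Oracle suites run on graphs small enough for exhaustive enumeration
(≤ 8 nodes; spanning-tree enumeration at ≤ 7): MST cost against the
enumerated minimum, critical-path weight against simple-path enumeration,
shortest-path hops against a BFS reimplementation, linked-list scans
against full-scan filters, topological orders against every Stage edge;
200 seeded instances per suite plus derandomized hypothesis properties for
ingestion conservation, permutation invariance, segmentation covering and
standardization idempotence. The synthetic recovery rate for the planted
combination under 200 background edges is tabulated over 100 seeds.
Problem sizes were chosen so the whole suite runs in well under a minute
on one core while keeping the enumeration oracles exhaustive.

## Known limitations

* No text extraction: the pipeline starts at the quintuple level.
* No OWL/RDF reasoning; the ontology is a typed vocabulary.
* No persistence engine; graphs are session-scoped, exported to files, and
  the Cypher exporter produces scripts rather than executing them (MERGE
  semantics, so re-running a script cannot duplicate knowledge).
* Dose parsing covers the documented pattern family only; anything else is
  preserved as a raw note.
* The entropy-reduction framing sometimes attached to weighted critical
  paths is not formalized here; no entropy quantity is computed.
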