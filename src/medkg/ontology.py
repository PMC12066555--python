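"""Medication-ontology schema: concept terms, MT/AMT entries, relation
vocabulary and category-pair rules.

The schema is a typed vocabulary, not an axiom system.  A medication type
(MT, e.g. "beta-blockers") owns a set of attribute entries (AMT, e.g.
"β-Indications"), each mapped to one ontological concept term (e.g.
"Indications").  Relations form a closed vocabulary; category-pair rules are
advisory samples describing which relations were observed between which
entity categories.

Name matching is case-insensitive after Unicode NFC normalization, with an
alias table absorbing singular/plural and editorial variants ("Drug" vs
"Drugs", "Treatment methods" vs "Therapeutic approaches").  Names are stored
in their canonical as-loaded form.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

__all__ = [
    "ConceptTerm",
    "AmtEntry",
    "RelationType",
    "CategoryPairRule",
    "OntologySchema",
    "SchemaError",
    "ValidationReport",
    "canon",
    "load_schema",
    "write_schema",
    "schema_stats",
    "validate_quintuple",
    "packaged_schema",
]

#: Provenance flags: guideline, expert consensus, standards, schemes,
#: real outpatient data, expert clinical experience.
PROVENANCE_FLAGS = frozenset({"G", "EC", "St", "Sc", "R", "EE"})


def canon(name: str) -> str:
    """Canonical matching key: NFC-normalized, casefolded, stripped."""
    return unicodedata.normalize("NFC", name).strip().casefold()


def _deplural(key: str) -> str:
    return key[:-1] if key.endswith("s") else key


class SchemaError(ValueError):
    """Raised when schema tables violate structural invariants."""


@dataclass(frozen=True)
class ConceptTerm:
    name: str
    sources: frozenset = frozenset()
    aliases: frozenset = frozenset()

    def matches(self, name: str) -> bool:
        key = canon(name)
        if key == canon(self.name):
            return True
        return any(key == canon(a) for a in self.aliases)


@dataclass(frozen=True)
class AmtEntry:
    """One attribute-of-medication-type entry (an AMT ontology row)."""

    mt: str
    amt_name: str
    concept_term: str


@dataclass(frozen=True)
class RelationType:
    name: str
    sources: frozenset = frozenset()


@dataclass(frozen=True)
class CategoryPairRule:
    subject_category: str
    object_category: str
    allowed_relations: frozenset

    def allows(self, relation: str) -> bool:
        key = canon(relation)
        return any(key == canon(r) for r in self.allowed_relations)


@dataclass
class OntologySchema:
    mts: list = field(default_factory=list)
    amts: list = field(default_factory=list)
    concept_terms: list = field(default_factory=list)
    relations: list = field(default_factory=list)
    pair_rules: list = field(default_factory=list)
    #: References that could not be cross-resolved but are kept, e.g.
    #: pair-rule relations outside the declared relation vocabulary.
    unresolved: list = field(default_factory=list)

    # -- lookups ----------------------------------------------------------
    def resolve_concept(self, name: str) -> Optional[ConceptTerm]:
        for ct in self.concept_terms:
            if ct.matches(name):
                return ct
        return None

    def known_relation(self, name: str) -> bool:
        key = canon(name)
        if any(key == canon(r.name) for r in self.relations):
            return True
        # pair-rule vocabulary is a sample broader than the declared list
        for rule in self.pair_rules:
            if rule.allows(name):
                return True
        return False

    def known_category(self, name: str) -> bool:
        if self.resolve_concept(name) is not None:
            return True
        key = canon(name)
        if key in {"mt", "amt"}:
            return True
        return any(key == canon(m) for m in self.mts)

    def pair_rules_for(self, sub_category: str, obj_category: str):
        """Rules whose category pair matches the given quintuple categories."""
        return [
            r
            for r in self.pair_rules
            if self._cat_matches(r.subject_category, sub_category)
            and self._cat_matches(r.object_category, obj_category)
        ]

    # Entity-like concepts are never matched by the generic "AMT" bucket of
    # the pair-rule table.
    _ENTITY_LIKE = frozenset(
        {
            "drugs", "drug combinations", "diseases", "patients", "symptoms",
            "combination medications", "therapeutic approaches", "mt",
        }
    )

    def _cat_matches(self, rule_cat: str, quintuple_cat: str) -> bool:
        rc, qc = canon(rule_cat), canon(quintuple_cat)
        if rc == qc or _deplural(rc) == _deplural(qc):
            return True
        ct = self.resolve_concept(quintuple_cat)
        if ct is not None:
            cname = canon(ct.name)
            if rc == cname or _deplural(rc) == _deplural(cname):
                return True
            if rc == "amt" and cname not in self._ENTITY_LIKE:
                return True
        elif rc == "amt" and qc == "amt":
            return True
        return False


@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# loading / writing

TableLike = Union[str, Path, pd.DataFrame, None]


def _as_frame(table: TableLike, columns: list) -> pd.DataFrame:
    if table is None:
        return pd.DataFrame(columns=columns)
    if isinstance(table, pd.DataFrame):
        df = table
    else:
        df = pd.read_csv(table, sep="\t", dtype=str)
    df = df.fillna("")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"schema table missing columns: {missing}")
    return df


def _split_flags(cell: str) -> frozenset:
    return frozenset(p.strip() for p in str(cell).split(";") if p.strip())


def load_schema(
    amt: TableLike = None,
    concepts: TableLike = None,
    relations: TableLike = None,
    pair_rules: TableLike = None,
    mts: Optional[Iterable[str]] = None,
) -> OntologySchema:
    """Load and cross-reference an ontology schema from tabular inputs.

    Each argument is a path to a UTF-8 TSV (or an equivalent DataFrame);
    any table may be omitted.  Duplicate (mt, amt_name) pairs and AMT rows
    citing undeclared concept terms raise :class:`SchemaError` naming every
    offender.  Pair-rule relations absent from the declared relation
    vocabulary are collected on ``schema.unresolved`` rather than dropped.
    """
    schema = OntologySchema()

    cdf = _as_frame(concepts, ["concept"])
    seen = set()
    for _, row in cdf.iterrows():
        name = row["concept"].strip()
        if not name:
            continue
        if canon(name) in seen:
            raise SchemaError(f"duplicate concept term: {name!r}")
        seen.add(canon(name))
        aliases = _split_flags(row.get("aliases", ""))
        schema.concept_terms.append(
            ConceptTerm(name, _split_flags(row.get("sources", "")), aliases)
        )

    adf = _as_frame(amt, ["mt", "amt_name", "concept_term"])
    seen_pairs = set()
    bad_concepts = []
    for _, row in adf.iterrows():
        mt, amt_name, ct = (row["mt"].strip(), row["amt_name"].strip(),
                            row["concept_term"].strip())
        if not (mt and amt_name and ct):
            raise SchemaError(f"AMT row with empty field: {tuple(row)}")
        key = (canon(mt), canon(amt_name))
        if key in seen_pairs:
            raise SchemaError(f"duplicate AMT entry: ({mt!r}, {amt_name!r})")
        seen_pairs.add(key)
        if schema.concept_terms and schema.resolve_concept(ct) is None:
            bad_concepts.append((amt_name, ct))
        schema.amts.append(AmtEntry(mt, amt_name, ct))
    if bad_concepts:
        names = ", ".join(f"{a!r} -> {c!r}" for a, c in bad_concepts)
        raise SchemaError(f"AMT entries cite undeclared concept terms: {names}")

    rdf = _as_frame(relations, ["relation"])
    seen = set()
    for _, row in rdf.iterrows():
        name = row["relation"].strip()
        if not name:
            continue
        if canon(name) in seen:
            raise SchemaError(f"duplicate relation type: {name!r}")
        seen.add(canon(name))
        schema.relations.append(
            RelationType(name, _split_flags(row.get("sources", "")))
        )

    pdf = _as_frame(pair_rules, ["subject_category", "object_category", "relations"])
    seen_pairs = set()
    declared = {canon(r.name) for r in schema.relations}
    for _, row in pdf.iterrows():
        sub_c, obj_c = row["subject_category"].strip(), row["object_category"].strip()
        rels = _split_flags(row["relations"])
        if not rels:
            raise SchemaError(
                f"pair rule ({sub_c!r}, {obj_c!r}) has no relations"
            )
        key = (canon(sub_c), canon(obj_c))
        if key in seen_pairs:
            raise SchemaError(f"duplicate pair rule: ({sub_c!r}, {obj_c!r})")
        seen_pairs.add(key)
        for r in sorted(rels):
            if canon(r) not in declared:
                schema.unresolved.append(
                    f"pair rule ({sub_c}, {obj_c}): relation {r!r} not in "
                    "declared relation vocabulary"
                )
        schema.pair_rules.append(CategoryPairRule(sub_c, obj_c, rels))

    if mts is not None:
        schema.mts = list(dict.fromkeys(mts))
    else:
        schema.mts = list(dict.fromkeys(e.mt for e in schema.amts))
    return schema


def write_schema(schema: OntologySchema, out_dir: Union[str, Path]) -> dict:
    """Write a schema back to its four TSV tables; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["concepts"] = out / "concepts.tsv"
    pd.DataFrame(
        {
            "concept": [c.name for c in schema.concept_terms],
            "aliases": [";".join(sorted(c.aliases)) for c in schema.concept_terms],
            "sources": [";".join(sorted(c.sources)) for c in schema.concept_terms],
        }
    ).to_csv(paths["concepts"], sep="\t", index=False)

    paths["amt"] = out / "amt.tsv"
    pd.DataFrame(
        {
            "mt": [e.mt for e in schema.amts],
            "amt_name": [e.amt_name for e in schema.amts],
            "concept_term": [e.concept_term for e in schema.amts],
        }
    ).to_csv(paths["amt"], sep="\t", index=False)

    paths["relations"] = out / "relations.tsv"
    pd.DataFrame(
        {
            "relation": [r.name for r in schema.relations],
            "sources": [";".join(sorted(r.sources)) for r in schema.relations],
        }
    ).to_csv(paths["relations"], sep="\t", index=False)

    paths["pair_rules"] = out / "pair_rules.tsv"
    pd.DataFrame(
        {
            "subject_category": [r.subject_category for r in schema.pair_rules],
            "object_category": [r.object_category for r in schema.pair_rules],
            "relations": [";".join(sorted(r.allowed_relations)) for r in schema.pair_rules],
        }
    ).to_csv(paths["pair_rules"], sep="\t", index=False)
    return paths


def schema_stats(schema: OntologySchema) -> dict:
    """Cardinalities of the deduplicated schema components."""
    return {
        "n_mts": len({canon(m) for m in schema.mts}),
        "n_amts": len({(canon(e.mt), canon(e.amt_name)) for e in schema.amts}),
        "n_concept_terms": len({canon(c.name) for c in schema.concept_terms}),
        "n_relations": len({canon(r.name) for r in schema.relations}),
        "n_pair_rules": len(
            {(canon(r.subject_category), canon(r.object_category))
             for r in schema.pair_rules}
        ),
    }


def validate_quintuple(q, schema: OntologySchema, strict: bool = False) -> ValidationReport:
    """Check one quintuple against the schema.

    Unknown categories and relations are always violations.  Pair-rule
    findings (no rule covering the category pair, or a relation outside the
    rule's sample) are violations only under ``strict=True``; by default
    they are warnings, because the pair-rule table is an explicit sample.
    """
    report = ValidationReport()
    for cat, side in ((q.sub_type, "subject"), (q.obj_type, "object")):
        if not schema.known_category(cat):
            report.violations.append(f"unknown {side} category: {cat!r}")
    if not schema.known_relation(q.rel):
        report.violations.append(f"unknown relation: {q.rel!r}")
    if report.violations:
        return report

    if schema.pair_rules:
        rules = schema.pair_rules_for(q.sub_type, q.obj_type)
        finding = None
        if not rules:
            finding = (
                f"no pair rule for categories ({q.sub_type!r}, {q.obj_type!r})"
            )
        elif not any(r.allows(q.rel) for r in rules):
            finding = (
                f"relation {q.rel!r} not listed for pair "
                f"({q.sub_type!r}, {q.obj_type!r})"
            )
        if finding is not None:
            (report.violations if strict else report.warnings).append(finding)
    return report


def packaged_schema() -> OntologySchema:
    """The beta-blocker schema shipped with the package."""
    from .fixtures import fixture_path

    return load_schema(
        amt=fixture_path("bb_amt.tsv"),
        concepts=fixture_path("concepts.tsv"),
        relations=fixture_path("relations.tsv"),
        pair_rules=fixture_path("pair_rules.tsv"),
    )
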