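"""Term standardization and dictionary-assisted segmentation.

Two auxiliary lexicons — a drug pharmacopoeia and a disease codex — drive
greedy longest-match segmentation (so multi-word clinical terms such as
"acute myocardial infarction" survive as single tokens) and alias
unification on an already-built graph.  Standardization rules come in five
kinds applied in a fixed order: category unification, synonym unification,
expression normalization, reference filling (which may split one term into
several), and redundancy simplification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple, Union

import pandas as pd
import yaml

from .kg_core import PropertyGraph
from .ontology import canon

__all__ = [
    "Lexicon",
    "RuleKind",
    "StandardizationRule",
    "Token",
    "load_lexicon",
    "load_rules",
    "standardize_term",
    "segment_text",
    "merge_aliases",
    "packaged_lexicons",
    "packaged_rules",
]


class RuleKind(Enum):
    """The five standardization rule kinds, in application order."""

    category_unification = 1
    synonym = 2
    expression_normalization = 3
    reference_fill = 4
    redundancy_simplification = 5


@dataclass(frozen=True)
class StandardizationRule:
    kind: RuleKind
    pattern: str
    replacement: Tuple[str, ...]

    def __post_init__(self):
        if not self.replacement:
            raise ValueError(f"rule {self.pattern!r} has empty replacement")


@dataclass
class Lexicon:
    name: str
    terms: set = field(default_factory=set)
    aliases: Dict[str, str] = field(default_factory=dict)  # canon(alias) -> term

    def resolve(self, term: str) -> str:
        """Follow the alias map to a canonical term (transitively)."""
        current, seen = term, set()
        while canon(current) in self.aliases and canon(current) not in seen:
            seen.add(canon(current))
            current = self.aliases[canon(current)]
        return current

    def __contains__(self, term: str) -> bool:
        key = canon(term)
        return any(key == canon(t) for t in self.terms) or key in self.aliases


@dataclass(frozen=True)
class Token:
    text: str
    source: Optional[str] = None  # lexicon name, or None for fallback tokens


# ---------------------------------------------------------------------------
# loading


def load_lexicon(path: Union[str, Path], name: Optional[str] = None) -> Lexicon:
    """Read a TSV lexicon with columns ``term`` and ``alias_of``.

    Rows with an empty ``alias_of`` declare canonical terms; the rest map an
    alias onto another term (chains are allowed and resolved transitively).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "term" not in df.columns:
        raise ValueError(f"lexicon {path} lacks a 'term' column")
    lex = Lexicon(name or Path(path).stem)
    for _, row in df.iterrows():
        term = row["term"].strip()
        if not term:
            continue
        target = str(row.get("alias_of", "")).strip()
        lex.terms.add(term)
        if target:
            if canon(target) == canon(term):
                raise ValueError(f"alias {term!r} maps to itself")
            lex.aliases[canon(term)] = target
    for alias, target in lex.aliases.items():
        if not any(canon(t) == canon(target) for t in lex.terms):
            raise ValueError(
                f"alias target {target!r} is not a lexicon term"
            )
    return lex


def load_rules(path: Union[str, Path]) -> List[StandardizationRule]:
    """Load standardization rules from YAML; duplicated patterns with
    conflicting replacements within one kind are a configuration error."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    rules = []
    seen: Dict[Tuple[RuleKind, str], Tuple[str, ...]] = {}
    for entry in doc.get("rules", []):
        kind = RuleKind[entry["kind"]]
        pattern = str(entry["pattern"])
        replacement = tuple(str(r) for r in entry["replacement"])
        key = (kind, canon(pattern))
        if key in seen and seen[key] != replacement:
            raise ValueError(
                f"conflicting {kind.name} rules for pattern {pattern!r}"
            )
        seen[key] = replacement
        rules.append(StandardizationRule(kind, pattern, replacement))
    return rules


# ---------------------------------------------------------------------------
# operations


def standardize_term(term: str, rules: Iterable[StandardizationRule]) -> List[str]:
    """Apply the five rule kinds in order; unmatched input passes through.

    Whole-term patterns are matched case-insensitively after NFC
    normalization.  A reference-fill rule may fan one term out into several;
    later kinds are applied to each produced term.  The operation is
    idempotent for rule sets whose replacements are fixed points.
    """
    if not term.strip():
        raise ValueError("term is empty")
    by_kind: Dict[RuleKind, Dict[str, Tuple[str, ...]]] = {}
    for r in rules:
        by_kind.setdefault(r.kind, {})[canon(r.pattern)] = r.replacement

    current = [term]
    for kind in sorted(RuleKind, key=lambda k: k.value):
        table = by_kind.get(kind, {})
        nxt: List[str] = []
        for t in current:
            nxt.extend(table.get(canon(t), (t,)))
        current = nxt
    return current


_CJK_RANGES = (
    (0x4E00, 0x9FFF), (0x3400, 0x4DBF), (0xF900, 0xFAFF),
)


def _is_cjk(ch: str) -> bool:
    cp = ord(ch)
    return any(lo <= cp <= hi for lo, hi in _CJK_RANGES)


def segment_text(text: str, lexicons: List[Lexicon]) -> List[Token]:
    """Greedy longest-match segmentation, left to right.

    At each position the longest lexicon term starting there becomes one
    token (ties in length broken by lexicon order, so the pharmacopoeia can
    outrank the disease codex).  Elsewhere, CJK characters fall through to
    single-character tokens, whitespace to whitespace-run tokens, and other
    runs to word tokens.  Concatenating the token texts reproduces the input
    exactly.
    """
    if not text:
        raise ValueError("text is empty")

    def key(s: str) -> str:  # like canon() but without stripping, so a
        import unicodedata  # padded slice can never match a bare term

        return unicodedata.normalize("NFC", s).casefold()

    index: Dict[str, str] = {}
    max_len = 0
    for lex in lexicons:
        for t in list(lex.terms) + list(lex.aliases):
            index.setdefault(key(t.strip()), lex.name)
            max_len = max(max_len, len(t.strip()))

    def match_at(i: int) -> Optional[Tuple[int, str]]:
        top = min(max_len, len(text) - i)
        for length in range(top, 0, -1):
            src = index.get(key(text[i:i + length]))
            if src is not None:
                return length, src
        return None

    tokens: List[Token] = []
    i = 0
    while i < len(text):
        hit = match_at(i)
        if hit is not None:
            length, src = hit
            tokens.append(Token(text[i:i + length], src))
            i += length
            continue
        ch = text[i]
        if ch.isspace():
            j = i
            while j < len(text) and text[j].isspace():
                j += 1
            tokens.append(Token(text[i:j]))
            i = j
        elif _is_cjk(ch):
            tokens.append(Token(ch))
            i += 1
        else:
            j = i + 1
            while (j < len(text) and not text[j].isspace()
                   and not _is_cjk(text[j]) and match_at(j) is None):
                j += 1
            tokens.append(Token(text[i:j]))
            i = j
    return tokens


def merge_aliases(graph: PropertyGraph, lexicons: List[Lexicon]):
    """Merge nodes whose names alias the same canonical term.

    Only same-category nodes merge; a would-be merge across categories is
    skipped and reported.  Incident edges are re-attached to the merged
    node, and parallel edges produced by a merge coalesce with weight
    addition, so total edge weight is conserved.  Returns (new graph,
    report) where the report lists every merge and skip.
    """
    def resolve(name: str) -> str:
        for lex in lexicons:
            if canon(name) in lex.aliases:
                return lex.resolve(name)
        return name

    groups: Dict[Tuple[str, str], list] = {}
    for node in graph.nodes():
        target = resolve(node.name)
        groups.setdefault((canon(target), canon(node.category)), []).append(node)

    # cross-category collisions on the same canonical name: report, no merge
    report = {"merges": [], "skipped": []}
    by_name: Dict[str, set] = {}
    for (cname, ccat), members in groups.items():
        by_name.setdefault(cname, set()).add(ccat)
    for cname, cats in sorted(by_name.items()):
        if len(cats) > 1:
            report["skipped"].append(
                f"name {cname!r} spans categories {sorted(cats)}; not merged "
                "across categories"
            )

    merged = PropertyGraph()
    node_map: Dict[int, int] = {}
    for (cname, _ccat), members in sorted(
        groups.items(), key=lambda kv: min(n.node_id for n in kv[1])
    ):
        display = resolve(members[0].name)
        attrs: Dict[str, str] = {}
        for n in sorted(members, key=lambda n: n.node_id):
            attrs.update(n.attributes)
        nid = merged.add_node(display, members[0].category, attrs)
        for n in members:
            node_map[n.node_id] = nid
        if len(members) > 1:
            report["merges"].append(
                {
                    "canonical": display,
                    "category": members[0].category,
                    "merged_names": sorted(n.name for n in members),
                }
            )
    for e in graph.edges():
        merged.add_edge(node_map[e.start_node], e.label, node_map[e.end_node],
                        weight=e.weight, attributes=dict(e.attributes))
    return merged, report


# ---------------------------------------------------------------------------
# packaged resources


def packaged_lexicons() -> List[Lexicon]:
    """The shipped pharmacopoeia and disease codex, in priority order."""
    from .fixtures import fixture_path

    return [
        load_lexicon(fixture_path("pharmacopoeia.tsv"), "pharmacopoeia"),
        load_lexicon(fixture_path("disease_codex.tsv"), "disease_codex"),
    ]


def packaged_rules() -> List[StandardizationRule]:
    from .fixtures import fixture_path

    return load_rules(fixture_path("standardization_rules.yaml"))
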