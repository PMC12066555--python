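"""Packaged fixture access: the beta-blocker schema tables, the six
case-study quintuple tables, and the shipped lexicons."""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import List, Optional, Sequence

from .kg_core import PropertyGraph, Quintuple, ingest_quintuples

#: Case-study sections and their packaged quintuple tables.
SECTIONS = {
    "multi_use": "bb_341_multi_use.tsv",
    "synergy": "bb_342_synergy.tsv",
    "mst": "bb_343_mst.tsv",
    "intersection": "bb_344_intersection.tsv",
    "comorbidity": "bb_345_comorbidity.tsv",
    "stages": "bb_346_stages.tsv",
}


def fixture_path(name: str) -> Path:
    path = resources.files("medkg").joinpath("data", name)
    return Path(str(path))


def load_section_rows(section: str) -> List[Quintuple]:
    """Quintuple rows of one beta-blocker case-study section."""
    from .io import read_quintuple_table

    if section not in SECTIONS:
        raise KeyError(f"unknown section {section!r}; one of {sorted(SECTIONS)}")
    rows, diagnostics = read_quintuple_table(fixture_path(SECTIONS[section]))
    if diagnostics:  # packaged tables are clean by construction
        raise RuntimeError(f"fixture {section} has bad rows: {diagnostics}")
    return rows


def load_beta_blocker_graph(sections: Optional[Sequence[str]] = None,
                            schema=None) -> PropertyGraph:
    """Graph over one or more case-study sections (all six by default)."""
    rows: List[Quintuple] = []
    for section in sections or list(SECTIONS):
        rows.extend(load_section_rows(section))
    return ingest_quintuples(rows, schema=schema)
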