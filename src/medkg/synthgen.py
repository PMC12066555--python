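"""Seeded synthetic knowledge-graph generator with planted, recoverable
reasoning patterns.

The generator emits quintuple tables shaped like the medication ontology
(MT / drug / disease / symptom / treatment-method categories, the packaged
relation vocabulary) so every reasoning operation can be exercised without
external data.  Planted patterns carry their expected answers as ground
truth; with zero background edges each pattern is recovered exactly by the
corresponding reasoning operation.  Output depends only on (seed, config):
one integer seed drives a single numpy Generator stream, and node names are
readable tokens ("drug_017") so failing tests are debuggable.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .kg_core import Quintuple

__all__ = [
    "MultiUsePattern",
    "SynergyPattern",
    "DosageTreePattern",
    "IntersectionPattern",
    "StageChainPattern",
    "SynthConfig",
    "GroundTruth",
    "SynthConfigError",
    "generate",
]


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class MultiUsePattern:
    """A drug connected to ``n_diseases`` planted diseases at ``depth`` hops
    (depth-1 intermediate attribute nodes per chain)."""

    drug: str
    n_diseases: int
    depth: int = 1


@dataclass(frozen=True)
class SynergyPattern:
    """A disease tied to a drug-combination node by a weight-boosted
    "combined effect" edge; the combination contains the given drugs."""

    disease: str
    drugs: Tuple[str, ...]
    weight_boost: int = 3


@dataclass(frozen=True)
class DosageTreePattern:
    """A drug with per-indication dosing attribute nodes and adverse
    reactions, shaped like the propranolol dosing subtree."""

    drug: str
    indications: Tuple[Tuple[str, Tuple[Tuple[str, str], ...]], ...]
    adverse_reactions: Tuple[str, ...] = ()


@dataclass(frozen=True)
class IntersectionPattern:
    symptom_a: str
    symptom_b: str
    shared: str
    treatment: str


@dataclass(frozen=True)
class StageChainPattern:
    disease: str
    length: int
    treatments_per_stage: int = 1


@dataclass
class SynthConfig:
    seed: int = 0
    n_drugs: int = 10
    n_diseases: int = 10
    n_symptoms: int = 5
    n_amts: int = 5
    n_background_edges: int = 0
    planted: list = field(default_factory=list)


@dataclass
class GroundTruth:
    multi_use: Dict[str, dict] = field(default_factory=dict)
    synergy: Dict[str, dict] = field(default_factory=dict)
    dosage: Dict[str, dict] = field(default_factory=dict)
    intersection: List[dict] = field(default_factory=list)
    stages: Dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# Attribute values carry their units ("10 mg", "2–3 times daily", "tablet").
_DOSE_TEMPLATES = {
    "initial_dose": "initial dose of {}",
    "max_dose": "maximum dosage of {}",
    "dose_range": "dosage range of {}",
    "frequency": "{}",
    "form": "{} form",
}


def _validate(config: SynthConfig) -> None:
    for name in ("n_drugs", "n_diseases", "n_symptoms", "n_amts",
                 "n_background_edges"):
        if getattr(config, name) < 0:
            raise SynthConfigError(f"{name} must be >= 0")
    for p in config.planted:
        if isinstance(p, MultiUsePattern):
            if p.depth < 1:
                raise SynthConfigError(f"multi_use depth must be >= 1 ({p})")
            if p.n_diseases < 1:
                raise SynthConfigError(f"multi_use needs >= 1 disease ({p})")
        elif isinstance(p, SynergyPattern):
            if p.weight_boost < 1 or not p.drugs:
                raise SynthConfigError(f"invalid synergy pattern {p}")
        elif isinstance(p, DosageTreePattern):
            if not p.indications:
                raise SynthConfigError(f"dosage tree needs indications ({p})")
        elif isinstance(p, IntersectionPattern):
            if len({p.symptom_a, p.symptom_b, p.shared}) != 3:
                raise SynthConfigError(f"intersection names must differ ({p})")
        elif isinstance(p, StageChainPattern):
            if p.length < 1:
                raise SynthConfigError(f"stage chain length must be >= 1 ({p})")
        else:
            raise SynthConfigError(f"unknown pattern type {type(p).__name__}")


def generate(config: SynthConfig) -> Tuple[List[Quintuple], GroundTruth]:
    """Emit (quintuple rows, ground truth) for a config; deterministic in
    (seed, config).  Unsatisfiable patterns raise before any output."""
    _validate(config)
    rng = np.random.default_rng(config.seed)
    rows: List[Quintuple] = []
    truth = GroundTruth()

    drugs = [f"drug_{i:03d}" for i in range(config.n_drugs)]
    diseases = [f"disease_{i:03d}" for i in range(config.n_diseases)]
    symptoms = [f"symptom_{i:03d}" for i in range(config.n_symptoms)]
    amts = [f"amt_{i:03d}" for i in range(config.n_amts)]

    def emit(sub, sub_t, rel, obj, obj_t, n=1):
        for _ in range(n):
            rows.append(Quintuple(sub, sub_t, rel, obj, obj_t))

    for p in config.planted:
        if isinstance(p, MultiUsePattern):
            planted_diseases = []
            for j in range(p.n_diseases):
                chain = [(p.drug, "Drugs")]
                for hop in range(p.depth - 1):
                    chain.append((f"{p.drug}_amt_{j}_{hop}", "Indications"))
                target = f"{p.drug}_disease_{j}"
                chain.append((target, "Diseases"))
                planted_diseases.append(target)
                for (a, at), (b, bt) in zip(chain, chain[1:]):
                    rel = "Indications" if bt == "Diseases" else "AT"
                    emit(a, at, rel, b, bt)
            truth.multi_use[p.drug] = {
                "diseases": planted_diseases, "depth": p.depth,
            }
            drugs.append(p.drug)
            diseases.extend(planted_diseases)
        elif isinstance(p, SynergyPattern):
            combo = f"{p.disease}_combo"
            emit(p.disease, "Diseases", "The combined effect is better than",
                 combo, "Drug combinations", n=p.weight_boost)
            for d in p.drugs:
                emit(combo, "Drug combinations", "Drug combination", d, "Drugs")
            truth.synergy[p.disease] = {
                "combination": combo, "drugs": sorted(p.drugs),
                "weight": p.weight_boost,
            }
            diseases.append(p.disease)
            drugs.extend(p.drugs)
        elif isinstance(p, DosageTreePattern):
            expected = {}
            for indication, attrs in p.indications:
                emit(p.drug, "Drugs", "Indications", indication, "Diseases")
                record = {}
                for key, value in attrs:
                    template = _DOSE_TEMPLATES.get(key)
                    if template is None:
                        raise SynthConfigError(
                            f"dosage attribute {key!r} not supported"
                        )
                    if key == "form":
                        emit(p.drug, "Drugs", "Properties",
                             template.format(value), "Drug applications")
                    else:
                        emit(indication, "Diseases", "Properties",
                             template.format(value), "Drug applications")
                    record[key] = value
                expected[indication] = record
            for ar in p.adverse_reactions:
                emit(p.drug, "Drugs", "Causes", ar, "Adverse reactions")
            truth.dosage[p.drug] = {
                "indications": expected,
                "adverse_reactions": sorted(p.adverse_reactions),
            }
            drugs.append(p.drug)
        elif isinstance(p, IntersectionPattern):
            emit(p.symptom_a, "Symptoms", "Shows", p.shared, "Symptoms")
            emit(p.symptom_b, "Symptoms", "Shows", p.shared, "Symptoms")
            emit(p.treatment, "MT", "Treatment", p.shared, "Symptoms")
            truth.intersection.append(
                {
                    "symptoms": [p.symptom_a, p.symptom_b],
                    "shared": p.shared, "treatment": p.treatment,
                }
            )
            symptoms.extend([p.symptom_a, p.symptom_b, p.shared])
        elif isinstance(p, StageChainPattern):
            stages = [f"{p.disease} stage {i + 1}" for i in range(p.length)]
            per_stage = {}
            for a, b in zip(stages, stages[1:]):
                emit(a, "Diseases", "Stage", b, "Diseases")
            for i, stage in enumerate(stages):
                names = [
                    f"{p.disease} stage {i + 1} treatment {t + 1}"
                    for t in range(p.treatments_per_stage)
                ]
                for t in names:
                    emit(t, "Treatment methods", "Treatment", stage, "Diseases")
                per_stage[stage] = names
            truth.stages[p.disease] = {
                "order": stages, "treatments": per_stage,
            }
            diseases.extend(stages)

    # background edges over schema-allowed category-pair templates; pools
    # include planted entities, so noise can interfere with recovery
    templates = [
        ("Drugs", drugs, "Treatment", "Diseases", diseases),
        ("Drugs", drugs, "Indications", "Diseases", diseases),
        ("Drugs", drugs, "Properties", "Drug applications", amts),
        ("Symptoms", symptoms, "Shows", "Symptoms", symptoms),
        ("Diseases", diseases, "Contains", "Diseases", diseases),
        ("Drugs", drugs, "Causes", "Symptoms", symptoms),
    ]
    templates = [t for t in templates if t[1] and t[4]]
    if config.n_background_edges and not templates:
        raise SynthConfigError("no entity pools available for background edges")
    for _ in range(config.n_background_edges):
        sub_t, pool_a, rel, obj_t, pool_b = templates[
            int(rng.integers(len(templates)))]
        a = pool_a[int(rng.integers(len(pool_a)))]
        b = pool_b[int(rng.integers(len(pool_b)))]
        if a == b:
            continue  # no accidental self-loops
        emit(a, sub_t, rel, b, obj_t)

    return rows, truth
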