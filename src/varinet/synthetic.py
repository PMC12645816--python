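"""Seed-controlled synthetic corpus generator.

The generator emulates the statistical structure the pipeline assumes,
without emulating curation realism the filters never touch:

* a gene universe and a complexome of disjoint-by-default gene sets,
* a tab-file corpus of bait–prey evidence stratified over bait sequence
  forms (reference plus point variants), carrying dataset annotations,
  host-tissue fields, interaction-type CV terms, mutation features and a
  bounded Beta-distributed confidence score,
* a causal-regulation table in the regulator/target/causality shape.

Differential signal is planted by construction: each variant's exclusive
complexes have ALL members among that variant's preys with above-threshold
scores, and none of their members ever appears as a prey of another
variant.  Background ("noise") preys and the prey–prey evidence used for
network induction are shared across strata with a single score per
interaction, mirroring the fact that shared partners rest on the same
underlying experiments — so background coverage is identical across
networks and only the planted complexes can differ.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .enrichment import GeneSet, write_gmt, write_set_metadata
from .errors import ConfigurationError
from .mirna import CausalRecord
from .mitab import (
    CvTerm,
    Feature,
    Identifier,
    InteractionRecord,
    Organism,
    write_mitab,
)
from .network import label_to_hgvs

_ASSOCIATION = CvTerm("psi-mi", "MI:0914", "association")
_PHYSICAL = CvTerm("psi-mi", "MI:0915", "physical association")
_PROXIMITY = CvTerm("psi-mi", "MI:2364", "proximity")
_COLOCALIZATION = CvTerm("psi-mi", "MI:0403", "colocalization")
_SPOKE = CvTerm("psi-mi", "MI:1060", "spoke expansion")
_DETECTION = CvTerm("psi-mi", "MI:0004", "affinity chromatography technology")
_SOURCE = CvTerm("psi-mi", "MI:0469", "IntAct")
_MUTATION = CvTerm("psi-mi", "MI:0118", "mutation")
_PREY_MUTATION_TERMS = [
    CvTerm("psi-mi", "MI:0119", "mutation decreasing interaction"),
    CvTerm("psi-mi", "MI:0382", "mutation increasing interaction"),
    CvTerm("psi-mi", "MI:0573", "mutation disrupting interaction"),
]

CAUSALITY_VOCAB = ["Downregulates quantity by destabilisation", "NA"]


@dataclass
class SyntheticConfig:
    """The stated world of the synthetic benchmark (all values seed-controlled)."""

    seed: int = 0
    n_genes: int = 500
    n_complexes: int = 40
    size_range: tuple[int, int] = (3, 15)
    #: variant label -> number of bait records in that stratum
    variants: dict[str, int] = dc_field(
        default_factory=lambda: {"reference": 80, "P301L": 80, "V337M": 80}
    )
    #: variant label -> complexome indices fully covered only in that stratum
    planted_exclusive: dict[str, list[int]] = dc_field(
        default_factory=lambda: {"reference": [0, 1], "P301L": [2, 3], "V337M": [4, 5]}
    )
    score_beta: tuple[float, float] = (5.0, 2.0)
    min_score: float = 0.5
    mutation_fraction: float = 0.3
    host_tissues: tuple[str, ...] = ("hippocampus", "cerebral cortex", "neuron")
    dataset_tag: str = "alzheimers"
    overlap_rate: float = 0.0
    n_prey_prey_edges: int = 60
    colocalization_fraction: float = 0.10
    negative_fraction: float = 0.05
    spoke_fraction: float = 0.20
    causal_fraction: float = 0.05
    bait_accession: str = "P10636-8"
    bait_gene: str = "MAPT"

    def __post_init__(self):
        if self.n_genes < 1 or self.n_complexes < 1:
            raise ConfigurationError("all counts must be positive")
        if not (0.0 <= self.mutation_fraction <= 1.0):
            raise ConfigurationError("mutation_fraction outside [0, 1]")
        if self.size_range[0] < 1 or self.size_range[0] > self.size_range[1]:
            raise ConfigurationError("invalid size_range")
        for count in self.variants.values():
            if count < 1:
                raise ConfigurationError("per-variant interaction counts must be positive")
        for label in self.planted_exclusive:
            if label not in self.variants:
                raise ConfigurationError(f"planted variant {label!r} not in variants")
            for idx in self.planted_exclusive[label]:
                if not (0 <= idx < self.n_complexes):
                    raise ConfigurationError(f"planted complex index {idx} out of range")


def _universe(config: SyntheticConfig) -> list[str]:
    return [f"GENE{i:04d}" for i in range(config.n_genes)]


def gen_complexome(config: SyntheticConfig) -> tuple[list[GeneSet], list[str]]:
    """Sample the complexome. Deterministic under the seed; members are
    sampled without replacement within a complex; cross-complex overlap is
    drawn at ``overlap_rate`` (0 gives pairwise-disjoint sets)."""
    rng = np.random.default_rng(config.seed)
    universe = _universe(config)
    lo, hi = config.size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    unused = list(universe)
    used: list[str] = []
    sets: list[GeneSet] = []
    for i, size in enumerate(sizes):
        members: set[str] = set()
        for _ in range(int(size)):
            take_overlap = (
                used and rng.random() < config.overlap_rate and len(set(used) - members) > 0
            )
            if take_overlap:
                pool = sorted(set(used) - members)
            else:
                pool = [g for g in unused if g not in members]
                if not pool:
                    raise ConfigurationError(
                        "complexome infeasible: universe exhausted "
                        f"(n_complexes x sizes exceed {config.n_genes} genes)"
                    )
            gene = pool[int(rng.integers(len(pool)))]
            members.add(gene)
            if gene in unused:
                unused.remove(gene)
                used.append(gene)
        sets.append(
            GeneSet(
                id=f"CPX-SYN{i:03d}",
                name=f"synthetic complex {i}",
                members=frozenset(members),
                source_tag="SYNTHETIC_Complexes_v1",
                process_annotation=f"synthetic process {i % 7}",
            )
        )
    return sets, universe


def planted_truth(
    config: SyntheticConfig, complexome: list[GeneSet]
) -> dict[str, set[str]]:
    """Variant label -> the complex accessions planted exclusively there."""
    return {
        label: {complexome[i].id for i in idxs}
        for label, idxs in config.planted_exclusive.items()
    }


def _sample_score(rng: np.random.Generator, config: SyntheticConfig) -> float:
    a, b = config.score_beta
    return float(np.round(rng.beta(a, b), 2))


def _sample_high_score(rng: np.random.Generator, config: SyntheticConfig) -> float:
    # construction guarantee: planted evidence stays clear of the threshold
    floor = config.min_score + 0.01
    while True:
        s = _sample_score(rng, config)
        if s >= floor:
            return s


def _prey_identifier(gene: str) -> Identifier:
    return Identifier("uniprotkb", f"SYN-{gene}")


def _bait_feature(label: str) -> Feature:
    m = re.match(r"^[A-Z](\d+)[A-Z]$", label)
    if m:
        pos = m.group(1)
        return Feature(_MUTATION, f"{pos}-{pos}", label_to_hgvs(label))
    return Feature(_MUTATION, "?-?", f"p.{label}")


@dataclass(frozen=True)
class _PreyProfile:
    """Per-prey evidence attributes shared across the variant strata."""

    gene: str
    score: float
    tissue: str
    interaction_type: CvTerm
    negative: bool
    expansion: CvTerm | None
    prey_feature: Feature | None


def _noise_profile(
    gene: str, rng: np.random.Generator, config: SyntheticConfig
) -> _PreyProfile:
    u = rng.random()
    if u < config.colocalization_fraction:
        itype = _COLOCALIZATION
    elif u < config.colocalization_fraction + 0.25:
        itype = _PROXIMITY
    elif u < config.colocalization_fraction + 0.55:
        itype = _PHYSICAL
    else:
        itype = _ASSOCIATION
    feature = None
    if rng.random() < config.mutation_fraction:
        term = _PREY_MUTATION_TERMS[int(rng.integers(len(_PREY_MUTATION_TERMS)))]
        pos = int(rng.integers(2, 400))
        feature = Feature(term, f"{pos}-{pos}", None)
    return _PreyProfile(
        gene=gene,
        score=_sample_score(rng, config),
        tissue=str(rng.choice(config.host_tissues)),
        interaction_type=itype,
        negative=bool(rng.random() < config.negative_fraction),
        expansion=_SPOKE if rng.random() < config.spoke_fraction else None,
        prey_feature=feature,
    )


def _bait_record(
    profile: _PreyProfile, label: str, index: int, config: SyntheticConfig
) -> InteractionRecord:
    features_a = [] if label == "reference" else [_bait_feature(label)]
    features_b = [profile.prey_feature] if profile.prey_feature else []
    return InteractionRecord(
        id_a=Identifier("uniprotkb", config.bait_accession),
        id_b=_prey_identifier(profile.gene),
        aliases_a=[Identifier("uniprotkb", config.bait_gene, "gene name")],
        aliases_b=[Identifier("uniprotkb", profile.gene, "gene name")],
        detection_method=_DETECTION,
        publication_ids=[Identifier("pubmed", "12345678")],
        taxon_a=Organism(9606, "human"),
        taxon_b=Organism(9606, "human"),
        interaction_type=profile.interaction_type,
        source_db=_SOURCE,
        interaction_ids=[Identifier("intact", f"EBI-SYN-{label}-{index:04d}")],
        confidences=[("intact-miscore", profile.score)],
        expansion=profile.expansion,
        host=Organism(9606, profile.tissue),
        annotations=[("dataset", config.dataset_tag)],
        negative=profile.negative,
        features_a=features_a,
        features_b=features_b,
    )


def gen_interactions(
    config: SyntheticConfig, complexome: list[GeneSet]
) -> list[InteractionRecord]:
    """Generate the MITAB-writable corpus with planted differential signal."""
    rng = np.random.default_rng(config.seed + 1)
    planted_members: dict[str, list[str]] = {}
    all_planted: set[str] = set()
    for label, idxs in config.planted_exclusive.items():
        members = sorted(set().union(*(complexome[i].members for i in idxs)))
        planted_members[label] = members
        all_planted.update(members)
    for label, count in config.variants.items():
        planted = planted_members.get(label, [])
        if len(planted) > count:
            raise ConfigurationError(
                f"planted complexes for {label!r} need {len(planted)} preys, "
                f"budget is {count}"
            )

    noise_pool = sorted(set(_universe(config)) - all_planted)
    budgets = {
        label: count - len(planted_members.get(label, []))
        for label, count in config.variants.items()
    }
    n_shared = min(budgets.values())
    if n_shared > len(noise_pool):
        raise ConfigurationError("noise budget exceeds available non-planted genes")
    shared_genes = [
        noise_pool[i]
        for i in rng.choice(len(noise_pool), size=n_shared, replace=False)
    ]
    shared_profiles = [_noise_profile(g, rng, config) for g in shared_genes]

    records: list[InteractionRecord] = []
    for label in config.variants:
        index = 0
        for gene in planted_members.get(label, []):
            profile = _PreyProfile(
                gene=gene,
                score=_sample_high_score(rng, config),
                tissue=str(rng.choice(config.host_tissues)),
                interaction_type=_ASSOCIATION,
                negative=False,
                expansion=None,
                prey_feature=None,
            )
            records.append(_bait_record(profile, label, index, config))
            index += 1
        for profile in shared_profiles:
            records.append(_bait_record(profile, label, index, config))
            index += 1
        # Budget beyond the shared background core becomes replicate evidence
        # for already-shared preys (same profile, new interaction id): extra
        # records never change which genes a stratum covers, so background
        # coverage stays identical across strata by construction.
        extra = budgets[label] - n_shared
        for e in range(extra):
            if not shared_profiles:
                break
            records.append(
                _bait_record(shared_profiles[e % n_shared], label, index, config)
            )
            index += 1

    # prey–prey evidence among shared background partners (one copy; the
    # induced networks of every stratum draw on the same corpus)
    if len(shared_genes) >= 2 and config.n_prey_prey_edges > 0:
        for e in range(config.n_prey_prey_edges):
            i, j = rng.choice(len(shared_genes), size=2, replace=False)
            a, b = shared_genes[int(i)], shared_genes[int(j)]
            records.append(
                InteractionRecord(
                    id_a=_prey_identifier(a),
                    id_b=_prey_identifier(b),
                    aliases_a=[Identifier("uniprotkb", a, "gene name")],
                    aliases_b=[Identifier("uniprotkb", b, "gene name")],
                    detection_method=_DETECTION,
                    publication_ids=[Identifier("pubmed", "12345678")],
                    taxon_a=Organism(9606, "human"),
                    taxon_b=Organism(9606, "human"),
                    interaction_type=_ASSOCIATION,
                    source_db=_SOURCE,
                    interaction_ids=[Identifier("intact", f"EBI-SYN-PP-{e:04d}")],
                    confidences=[("intact-miscore", _sample_score(rng, config))],
                    host=Organism(9606, str(rng.choice(config.host_tissues))),
                    annotations=[("dataset", config.dataset_tag)],
                )
            )
    return records


def gen_causal(
    config: SyntheticConfig, complexome: list[GeneSet]
) -> list[CausalRecord]:
    """Assign synthetic miRNA regulators to a fraction of the universe."""
    rng = np.random.default_rng(config.seed + 2)
    universe = _universe(config)
    n_targets = int(round(config.causal_fraction * len(universe)))
    if n_targets == 0:
        return []
    targets = [
        universe[i] for i in rng.choice(len(universe), size=n_targets, replace=False)
    ]
    records = []
    mir_counter = 1
    for gene in targets:
        for _ in range(int(rng.integers(1, 3))):
            causality = CAUSALITY_VOCAB[0] if rng.random() < 0.8 else CAUSALITY_VOCAB[1]
            records.append(
                CausalRecord(
                    regulator=f"hsa-mir-{mir_counter}-5p",
                    target=gene,
                    causality=causality,
                    source="SYNTHETIC",
                )
            )
            mir_counter += 1
    return records


def write_bundle(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the full synthetic bundle in the formats the real pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    complexome, _ = gen_complexome(config)
    records = gen_interactions(config, complexome)
    causal = gen_causal(config, complexome)
    paths = {
        "mitab": outdir / "corpus.mitab",
        "gmt": outdir / "complexes.gmt",
        "metadata": outdir / "complexes.meta.tsv",
        "causal": outdir / "causal.tsv",
    }
    write_mitab(records, paths["mitab"])
    write_gmt(complexome, paths["gmt"])
    write_set_metadata(complexome, paths["metadata"])
    with open(paths["causal"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("Regulator\tRegulator target\tCausality\tSource\n")
        for rec in causal:
            fh.write(
                f"{rec.regulator}\t{rec.target}\t{rec.causality}\t{rec.source or ''}\n"
            )
    return paths
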