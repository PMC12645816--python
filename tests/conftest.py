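"""Shared fixtures: a record factory and one default synthetic bundle."""

from __future__ import annotations

import pytest

from varinet.enrichment import EnrichmentConfig
from varinet.filters import FilterSpec
from varinet.mitab import (
    CvTerm,
    Feature,
    Identifier,
    InteractionRecord,
    Organism,
)
from varinet.pipeline import RunConfig
from varinet.synthetic import SyntheticConfig, gen_complexome, write_bundle

ASSOCIATION = CvTerm("psi-mi", "MI:0914", "association")
PROXIMITY = CvTerm("psi-mi", "MI:2364", "proximity")
COLOCALIZATION = CvTerm("psi-mi", "MI:0403", "colocalization")
MUTATION = CvTerm("psi-mi", "MI:0118", "mutation")
MUT_DECREASING = CvTerm("psi-mi", "MI:0119", "mutation decreasing interaction")
MUT_INCREASING = CvTerm("psi-mi", "MI:0382", "mutation increasing interaction")
MUT_DISRUPTING = CvTerm("psi-mi", "MI:0573", "mutation disrupting interaction")


def make_record(
    acc_a="P10636-8",
    acc_b="Q00001",
    gene_a="MAPT",
    gene_b="VCP",
    interaction_id="EBI-1",
    score=0.7,
    interaction_type=ASSOCIATION,
    host=("9606", "hippocampus"),
    dataset="alzheimers",
    features_a=(),
    features_b=(),
    negative=False,
    expansion=None,
    alt_a=(),
    alt_b=(),
):
    """Build a minimal valid interaction record for tests."""
    return InteractionRecord(
        id_a=Identifier("uniprotkb", acc_a),
        id_b=Identifier("uniprotkb", acc_b),
        alt_ids_a=[Identifier("uniprotkb", a) for a in alt_a],
        alt_ids_b=[Identifier("uniprotkb", a) for a in alt_b],
        aliases_a=[Identifier("uniprotkb", gene_a, "gene name")] if gene_a else [],
        aliases_b=[Identifier("uniprotkb", gene_b, "gene name")] if gene_b else [],
        detection_method=CvTerm("psi-mi", "MI:0004", "affinity chromatography technology"),
        publication_ids=[Identifier("pubmed", "12345678")],
        taxon_a=Organism(9606, "human"),
        taxon_b=Organism(9606, "human"),
        interaction_type=interaction_type,
        source_db=CvTerm("psi-mi", "MI:0469", "IntAct"),
        interaction_ids=[Identifier("intact", interaction_id)],
        confidences=[("intact-miscore", score)] if score is not None else [],
        expansion=expansion,
        host=Organism(int(host[0]), host[1]) if host else None,
        annotations=[("dataset", dataset)] if dataset else [],
        negative=negative,
        features_a=list(features_a),
        features_b=list(features_b),
    )


def mutation_feature(term=MUTATION, text=None, range_text="301-301"):
    return Feature(term, range_text, text)


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def complexome(default_config):
    sets, universe = gen_complexome(default_config)
    return sets, universe


@pytest.fixture(scope="session")
def bundle(default_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(default_config, outdir)


def brain_filter_spec(**overrides):
    kwargs = dict(
        dataset_tag="alzheimers",
        interaction_types={"MI:0914", "MI:2364"},
        include_type_descendants=True,
        host_terms=[(9606, "hippocampus"), (9606, "cerebral cortex"), (9606, "neuron")],
        min_score=0.5,
    )
    kwargs.update(overrides)
    return FilterSpec(**kwargs)


def variant_run_config(bundle, outdir, **overrides):
    kwargs = dict(
        mitab_path=str(bundle["mitab"]),
        geneset_path=str(bundle["gmt"]),
        geneset_metadata_path=str(bundle["metadata"]),
        causal_path=str(bundle["causal"]),
        filter_spec=brain_filter_spec(),
        enrichment=EnrichmentConfig(),
        output_dir=str(outdir),
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)
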