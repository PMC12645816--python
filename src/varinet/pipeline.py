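"""End-to-end workflows.

Two protocols are orchestrated from a single config:

* the variant workflow — filter the corpus, stratify bait records by the
  bait's sequence form, enrich each stratum's partner list against the
  complexome, compare enrichment across strata and overlay miRNA causal
  regulation;
* the identifier-query workflow — select all records matching an accession
  prefix (canonical protein, isoforms, processed chains), optionally drop
  spoke-expanded binaries, enrich the partner list and summarise
  mutation-effect categories.

Every run writes a manifest recording parameters, input digests and
per-stage record counts; reruns over unchanged inputs are bit-for-bit
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import yaml

from . import __version__
from .differential import (
    DifferentialReport,
    compare,
    presence_matrix,
    write_differential_tsv,
    write_presence_json,
)
from .enrichment import (
    EnrichmentConfig,
    EnrichmentRow,
    enrich,
    read_gmt,
    read_long_tsv,
    write_report,
)
from .errors import ConfigurationError, VarinetError
from .filters import FilterSpec, effect_histogram
from .mirna import load_causal, overlay, write_overlay_tsv
from .mitab import read_mitab
from .network import (
    QueryNetwork,
    VariantForm,
    induced_network,
    partner_genes,
    stratify_by_bait_variant,
    write_edge_list,
    write_node_list,
)
from .mitab import Identifier


@dataclass
class RunConfig:
    mitab_path: str
    geneset_path: str
    causal_path: str | None = None
    geneset_metadata_path: str | None = None
    filter_spec: FilterSpec = dc_field(default_factory=FilterSpec)
    bait_accession: str = "P10636-8"
    variant_labels: list[str] | None = None  # None -> every non-empty stratum
    enrichment: EnrichmentConfig = dc_field(default_factory=EnrichmentConfig)
    differential_criterion: str = "reported"
    true_binary_only: bool = False
    output_dir: str = "varinet_out"
    seed: int = 0


@dataclass
class VariantRunResult:
    buckets: dict[str, int]
    networks: dict[str, QueryNetwork]
    enrichments: dict[str, list[EnrichmentRow]]
    report: DifferentialReport
    overlay: dict[str, list[tuple[str, str]]]
    manifest: dict


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_genesets(config: RunConfig):
    path = Path(config.geneset_path)
    if path.suffix == ".gmt":
        sets = read_gmt(path)
        if config.geneset_metadata_path:
            meta = {
                gs.id: gs for gs in read_long_tsv_metadata(config.geneset_metadata_path)
            }
            sets = [_merge_meta(gs, meta.get(gs.id)) for gs in sets]
        return sets
    return read_long_tsv(path, config.geneset_metadata_path)


def read_long_tsv_metadata(path: str | Path):
    """Metadata-only rows (id, name, source_tag, process) as member-less stubs."""
    import csv

    from .enrichment import GeneSet

    out = []
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)
        for cells in reader:
            if len(cells) >= 2:
                out.append(
                    GeneSet(
                        id=cells[0],
                        name=cells[1],
                        members=frozenset({"_"}),
                        source_tag=cells[2] if len(cells) > 2 else "",
                        process_annotation=cells[3] if len(cells) > 3 else None,
                    )
                )
    return out


def _merge_meta(gs, meta):
    from .enrichment import GeneSet

    if meta is None:
        return gs
    return GeneSet(
        id=gs.id,
        name=meta.name,
        members=gs.members,
        source_tag=meta.source_tag,
        process_annotation=meta.process_annotation,
    )


def run_variant_workflow(config: RunConfig) -> VariantRunResult:
    """filter → stratify → partner genes → induced network → enrich → compare → overlay."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_mitab(config.mitab_path)
    filtered, filter_log = config.filter_spec.apply(records)
    genesets = _load_genesets(config)
    metadata = {gs.id: gs for gs in genesets}

    bait_records = [
        r
        for r in filtered
        if any(
            acc.split("-")[0] == config.bait_accession.split("-")[0]
            for acc in (
                [r.id_a.accession, r.id_b.accession]
                + [i.accession for i in r.alt_ids_a]
                + [i.accession for i in r.alt_ids_b]
            )
        )
    ]
    buckets = stratify_by_bait_variant(bait_records, config.bait_accession)
    labels = config.variant_labels or [
        label for label, recs in buckets.items() if recs and label != "unclassified"
    ]
    missing = [label for label in labels if label not in buckets]
    if missing:
        raise ConfigurationError(f"no records for variant label(s): {missing}")

    networks: dict[str, QueryNetwork] = {}
    enrichments: dict[str, list[EnrichmentRow]] = {}
    all_genes: set[str] = set()
    for label in sorted(labels):
        partners = partner_genes(buckets[label], config.bait_accession)
        if not partners:
            continue
        variant = VariantForm(
            Identifier("uniprotkb", config.bait_accession), label
        )
        net = induced_network(
            partners, filtered, variant, true_binary_only=config.true_binary_only
        )
        networks[label] = net
        enrichments[label] = enrich(partners, genesets, config.enrichment)
        all_genes |= set(partners)
        write_edge_list(net, outdir / f"network_{label}.edges.tsv")
        write_node_list(net, outdir / f"network_{label}.nodes.txt")
        write_report(enrichments[label], outdir / f"enrichment_{label}.tsv")

    if len(enrichments) < 2:
        raise VarinetError(
            "variant workflow needs at least two non-empty strata to compare"
        )
    matrix = presence_matrix(
        enrichments, criterion=config.differential_criterion,
        alpha=config.enrichment.alpha,
    )
    reference = "reference" if "reference" in enrichments else sorted(enrichments)[0]
    report = compare(matrix, reference)
    write_differential_tsv(report, metadata, outdir / "differential.tsv")
    write_presence_json(matrix, outdir / "presence_matrix.json")

    overlay_map: dict[str, list[tuple[str, str]]] = {}
    if config.causal_path:
        causal = load_causal(config.causal_path)
        overlay_map = overlay(causal, all_genes)
        write_overlay_tsv(overlay_map, outdir / "mirna_overlay.tsv")

    manifest = {
        "tool": {"name": "varinet", "version": __version__},
        "workflow": "variant",
        "config": _config_dict(config),
        "inputs": _input_digests(config),
        "filter_log": filter_log,
        "buckets": {label: len(recs) for label, recs in sorted(buckets.items())},
        "networks": {
            label: {"nodes": len(net.nodes), "edges": len(net.edges)}
            for label, net in sorted(networks.items())
        },
        "enrichment_rows": {
            label: len(rows) for label, rows in sorted(enrichments.items())
        },
        "differential": {
            "reference": report.reference_label,
            "exclusive_to_reference": sorted(report.exclusive_to_reference),
            "exclusive_to_each_comparator": {
                k: sorted(v)
                for k, v in sorted(report.exclusive_to_each_comparator.items())
            },
            "shared_all": sorted(report.shared_all),
        },
        "overlay_genes": len(overlay_map),
    }
    _write_manifest(manifest, outdir / "manifest.json")
    return VariantRunResult(
        buckets={label: len(recs) for label, recs in buckets.items()},
        networks=networks,
        enrichments=enrichments,
        report=report,
        overlay=overlay_map,
        manifest=manifest,
    )


@dataclass
class QueryRunResult:
    selected: int
    partners: list[str]
    enrichment: list[EnrichmentRow]
    effect_histogram: dict[str, int]
    manifest: dict


def run_query_workflow(config: RunConfig) -> QueryRunResult:
    """select-by-identifier → optional true-binary restriction → enrich → effects."""
    if not config.filter_spec.identifier_pattern:
        raise ConfigurationError("query workflow requires an identifier pattern")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = read_mitab(config.mitab_path)
    selected, filter_log = config.filter_spec.apply(records)
    if config.true_binary_only:
        n = len(selected)
        selected = [r for r in selected if r.expansion is None]
        filter_log["spoke_expanded"] = n - len(selected)
        filter_log["kept"] = len(selected)

    bait = config.filter_spec.identifier_pattern.rstrip("*")
    partners = partner_genes(selected, bait)
    rows: list[EnrichmentRow] = []
    if partners:
        genesets = _load_genesets(config)
        rows = enrich(partners, genesets, config.enrichment)
        write_report(rows, outdir / "enrichment_query.tsv")
    hist = effect_histogram(selected, config.filter_spec.mutation_closure)

    with open(outdir / "selected_records.tsv", "w", encoding="utf-8") as fh:
        fh.write("interaction_id\tid_a\tid_b\tscore\n")
        for r in selected:
            rec_id = r.interaction_ids[0].accession if r.interaction_ids else ""
            score = next((v for k, v in r.confidences if k == "intact-miscore"), "")
            fh.write(f"{rec_id}\t{r.id_a.accession}\t{r.id_b.accession}\t{score}\n")

    manifest = {
        "tool": {"name": "varinet", "version": __version__},
        "workflow": "query",
        "config": _config_dict(config),
        "inputs": _input_digests(config),
        "filter_log": filter_log,
        "selected_records": len(selected),
        "partners": len(partners),
        "enrichment_rows": len(rows),
        "mutation_effect_histogram": dict(sorted(hist.items())),
    }
    _write_manifest(manifest, outdir / "manifest.json")
    return QueryRunResult(
        selected=len(selected),
        partners=partners,
        enrichment=rows,
        effect_histogram=hist,
        manifest=manifest,
    )


def _config_dict(config: RunConfig) -> dict:
    d = asdict(config)
    d["filter_spec"]["mutation_closure"] = sorted(
        config.filter_spec.mutation_closure
    )
    d["filter_spec"]["interaction_types"] = sorted(
        config.filter_spec.interaction_types
    )
    return d


def _input_digests(config: RunConfig) -> dict[str, str]:
    digests = {"mitab": _digest(config.mitab_path), "genesets": _digest(config.geneset_path)}
    if config.causal_path:
        digests["causal"] = _digest(config.causal_path)
    if config.geneset_metadata_path:
        digests["geneset_metadata"] = _digest(config.geneset_metadata_path)
    return digests


def _write_manifest(manifest: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML document (keys mirror the dataclasses)."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    fs = doc.pop("filter_spec", {})
    if "interaction_types" in fs:
        fs["interaction_types"] = set(fs["interaction_types"])
    if "host_terms" in fs:
        fs["host_terms"] = [tuple(t) for t in fs["host_terms"]]
    if "mutation_closure" in fs:
        fs["mutation_closure"] = frozenset(fs["mutation_closure"])
    ec = doc.pop("enrichment", {})
    return RunConfig(
        filter_spec=FilterSpec(**fs), enrichment=EnrichmentConfig(**ec), **doc
    )
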