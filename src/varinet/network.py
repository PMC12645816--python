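"""Variant stratification and query-network construction.

Records that involve the bait protein are partitioned by the sequence form
of the bait: no mutation feature on the bait participant means the reference
form; a feature whose HGVS-like protein-change text normalises to a short
label (``p.Pro301Leu`` -> ``P301L``) defines that variant's stratum; text
that cannot be normalised routes the record to an ``unclassified`` bucket
(never silently dropped).  Prey-side mutations do not open a stratum — they
stay in the reference bucket as effect annotations.

The per-stratum partner list then induces a network: only corpus records
whose BOTH endpoints map into the partner set become edges, i.e. no first
neighbours outside the partner set are ever pulled in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field

import networkx as nx

from . import ontology
from .errors import ProteinChangeError
from .filters import MISCORE_KEY, _mutation_features
from .mitab import Identifier, InteractionRecord, get_confidence

UNCLASSIFIED = "unclassified"
REFERENCE = "reference"

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

_SIMPLE_SUB = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")
_COMPLEX = re.compile(r"^p\.([A-Za-z0-9_]+(?:delins|del|ins|dup|fs)[A-Za-z0-9_]*)$")


@dataclass(frozen=True)
class VariantForm:
    base_accession: Identifier
    variant_label: str
    dbsnp_id: str | None = None


@dataclass
class QueryNetwork:
    """An induced interactome for one bait form."""

    variant: VariantForm
    nodes: set[str]
    edges: list[tuple[str, str, float | None, str]]
    provenance: list[str] = dc_field(default_factory=list)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for a, b, score, rec_id in self.edges:
            g.add_edge(a, b, score=score, interaction_id=rec_id)
        return g


def normalize_protein_change(text: str) -> str:
    """Normalise an HGVS-like protein change to a short variant label.

    Single substitutions map three-letter residues to one-letter
    (``p.Pro301Leu`` -> ``P301L``); multi-residue delins/del/ins strings are
    returned verbatim after stripping ``p.``.  Anything else raises
    :class:`ProteinChangeError`.
    """
    text = text.strip().strip('"')
    m = _SIMPLE_SUB.match(text)
    if m:
        ref, pos, alt = m.groups()
        if ref not in AA3_TO_1 or alt not in AA3_TO_1:
            raise ProteinChangeError(f"unknown residue code in {text!r}")
        return f"{AA3_TO_1[ref]}{pos}{AA3_TO_1[alt]}"
    m = _COMPLEX.match(text)
    if m:
        return m.group(1)
    raise ProteinChangeError(f"not an HGVS-like protein change: {text!r}")


def label_to_hgvs(label: str) -> str:
    """Inverse of :func:`normalize_protein_change` for simple substitutions."""
    m = re.match(r"^([A-Z])(\d+)([A-Z])$", label)
    if not m:
        raise ProteinChangeError(f"not a simple substitution label: {label!r}")
    ref, pos, alt = m.groups()
    return f"p.{AA1_TO_3[ref]}{pos}{AA1_TO_3[alt]}"


def _base_accession(accession: str) -> str:
    return accession.split("-", 1)[0]


def _participant_accessions(record: InteractionRecord, side: str) -> list[str]:
    if side == "A":
        return [record.id_a.accession] + [i.accession for i in record.alt_ids_a]
    return [record.id_b.accession] + [i.accession for i in record.alt_ids_b]


def bait_side(record: InteractionRecord, bait_accession: str) -> str | None:
    """Which participant carries the bait accession (isoforms/chains included)."""
    base = _base_accession(bait_accession)
    for side in ("A", "B"):
        for acc in _participant_accessions(record, side):
            if acc == bait_accession or _base_accession(acc) == base:
                return side
    return None


def stratify_by_bait_variant(
    records: list[InteractionRecord],
    bait_accession: str,
    mutation_closure: frozenset[str] = ontology.DEFAULT_MUTATION_CLOSURE,
) -> dict[str, list[InteractionRecord]]:
    """Partition bait records into reference / variant / unclassified strata.

    Every input record lands in exactly one bucket.  Records not involving
    the bait at all go to ``unclassified`` (caller should pre-select).
    """
    buckets: dict[str, list[InteractionRecord]] = {REFERENCE: []}
    for record in records:
        side = bait_side(record, bait_accession)
        if side is None:
            buckets.setdefault(UNCLASSIFIED, []).append(record)
            continue
        bait_feats = [
            f for s, f in _mutation_features(record, mutation_closure) if s == side
        ]
        labels = set()
        failed = False
        for feat in bait_feats:
            if not feat.text:
                failed = True
                continue
            try:
                labels.add(normalize_protein_change(feat.text))
            except ProteinChangeError:
                failed = True
        if len(labels) == 1:
            buckets.setdefault(labels.pop(), []).append(record)
        elif not labels and not failed:
            # prey-side mutations (if any) do not open a stratum
            buckets[REFERENCE].append(record)
        else:
            buckets.setdefault(UNCLASSIFIED, []).append(record)
    return buckets


_DEFAULT_ALIAS_PRIORITY = ("gene name", "gene name synonym", "locus name")


def _gene_symbol(
    record: InteractionRecord,
    side: str,
    alias_priority: tuple[str, ...] = _DEFAULT_ALIAS_PRIORITY,
) -> str:
    aliases = record.aliases_a if side == "A" else record.aliases_b
    for wanted in alias_priority:
        for alias in aliases:
            if (alias.description or "").lower() == wanted:
                return alias.accession.upper()
    primary = record.id_a if side == "A" else record.id_b
    return primary.accession.upper()


def partner_genes(
    records: list[InteractionRecord],
    bait_accession: str,
    alias_priority: tuple[str, ...] = _DEFAULT_ALIAS_PRIORITY,
) -> list[str]:
    """Ordered, de-duplicated gene symbols of the non-bait participants."""
    base = _base_accession(bait_accession)

    def is_bait(record: InteractionRecord, side: str) -> bool:
        return any(
            acc == bait_accession or _base_accession(acc) == base
            for acc in _participant_accessions(record, side)
        )

    seen: dict[str, None] = {}
    for record in records:
        side = bait_side(record, bait_accession)
        if side is None:
            continue
        prey = "B" if side == "A" else "A"
        if is_bait(record, prey):
            continue  # self-interaction: bait is never its own partner
        seen.setdefault(_gene_symbol(record, prey, alias_priority), None)
    return list(seen)


def induced_network(
    partner_set: list[str] | set[str],
    corpus_records: list[InteractionRecord],
    variant: VariantForm | None = None,
    true_binary_only: bool = False,
    alias_priority: tuple[str, ...] = _DEFAULT_ALIAS_PRIORITY,
) -> QueryNetwork:
    """Induced subgraph on ``partner_set``: edges need BOTH endpoints inside.

    No neighbour outside the partner set is ever added.  Spoke-expanded
    records are retained unless ``true_binary_only`` is set.  Edge score is
    the intact-miscore when present.
    """
    if not partner_set:
        raise ValueError("partner_set must be non-empty")
    members = {g.upper() for g in partner_set}
    if variant is None:
        variant = VariantForm(Identifier("unspecified", "query"), REFERENCE)
    seen_edges: set[tuple[str, str, str]] = set()
    edges: list[tuple[str, str, float | None, str]] = []
    provenance: list[str] = []
    for record in corpus_records:
        if true_binary_only and record.expansion is not None:
            continue
        ga = _gene_symbol(record, "A", alias_priority)
        gb = _gene_symbol(record, "B", alias_priority)
        if ga not in members or gb not in members or ga == gb:
            continue
        a, b = sorted((ga, gb))
        rec_id = record.interaction_ids[0].accession if record.interaction_ids else ""
        key = (a, b, rec_id)
        if key in seen_edges:
            continue
        seen_edges.add(key)
        edges.append((a, b, get_confidence(record, MISCORE_KEY), rec_id))
        provenance.append(rec_id)
    return QueryNetwork(variant=variant, nodes=members, edges=edges, provenance=provenance)


def write_edge_list(network: QueryNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tscore\tinteraction_id\n")
        for a, b, score, rec_id in sorted(network.edges):
            s = "" if score is None else f"{score:g}"
            fh.write(f"{a}\t{b}\t{s}\t{rec_id}\n")


def write_node_list(network: QueryNetwork, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(network.nodes):
            fh.write(gene + "\n")
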