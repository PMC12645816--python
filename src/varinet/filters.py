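"""Corpus-selection predicates and composable query profiles.

Each filter is a pure subset operation on a record list: output is a
subsequence of the input, so filters are idempotent and commute with each
other.  A :class:`FilterSpec` bundles the predicates the curated-corpus
protocol uses (dataset tag, mutation filter, interaction-type restriction,
host tissue profile, confidence threshold, taxon pair, identifier prefix)
and applies them while counting what each stage drops — the drop log is the
desk-reproducible stand-in for live-database corpus counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field

from . import ontology
from .errors import ConfigurationError
from .mitab import Feature, InteractionRecord, get_confidence

MISCORE_KEY = "intact-miscore"

#: Unicode hyphen variants normalised at comparison time only (never on disk).
_HYPHENS = {"‐": "-", "‑": "-", "‒": "-", "–": "-", "−": "-"}


def _norm(text: str) -> str:
    for bad, good in _HYPHENS.items():
        text = text.replace(bad, good)
    return text.casefold()


@dataclass
class FilterSpec:
    """A named query profile over the interaction corpus."""

    dataset_tag: str | None = None
    require_mutation: bool = False
    interaction_types: set[str] = dc_field(default_factory=set)
    include_type_descendants: bool = True
    host_terms: list[tuple[int, str]] = dc_field(default_factory=list)
    min_score: float | None = None
    taxon_pair: tuple[int, int] | None = None
    identifier_pattern: str | None = None
    mutation_closure: frozenset[str] = ontology.DEFAULT_MUTATION_CLOSURE
    exclude_negative: bool = True

    def __post_init__(self):
        if self.min_score is not None and not (0.0 <= self.min_score <= 1.0):
            raise ConfigurationError(f"min_score {self.min_score} outside [0, 1]")
        if self.identifier_pattern is not None:
            _validate_pattern(self.identifier_pattern)

    def apply(
        self, records: list[InteractionRecord]
    ) -> tuple[list[InteractionRecord], dict[str, int]]:
        """Apply every configured predicate; return (kept, per-stage drop counts)."""
        log: dict[str, int] = {"input": len(records)}
        out = records
        if self.exclude_negative:
            n = len(out)
            out = [r for r in out if not r.negative]
            log["negative"] = n - len(out)
        if self.dataset_tag:
            n = len(out)
            out = filter_dataset(out, self.dataset_tag)
            log["dataset"] = n - len(out)
        if self.require_mutation:
            n = len(out)
            out = filter_mutation(out, self.mutation_closure)
            log["mutation"] = n - len(out)
        if self.interaction_types:
            n = len(out)
            out = filter_interaction_type(
                out,
                self.interaction_types,
                include_descendants=self.include_type_descendants,
            )
            log["interaction_type"] = n - len(out)
        if self.host_terms:
            n = len(out)
            out = filter_host(out, self.host_terms)
            log["host"] = n - len(out)
        if self.taxon_pair is not None:
            n = len(out)
            out = filter_taxon_pair(out, self.taxon_pair)
            log["taxon_pair"] = n - len(out)
        if self.min_score is not None:
            n = len(out)
            out = filter_score(out, self.min_score)
            log["score"] = n - len(out)
        if self.identifier_pattern is not None:
            n = len(out)
            out = select_by_identifier(out, self.identifier_pattern)
            log["identifier"] = n - len(out)
        log["kept"] = len(out)
        return out, log


@dataclass(frozen=True)
class MutationEffect:
    """The direction a mutation feature imposes on an interaction."""

    category: str  # increasing | decreasing | disrupting | causing | unknown
    evidence: Feature


# ---------------------------------------------------------------------------
# individual predicates


def filter_dataset(
    records: list[InteractionRecord], tag: str
) -> list[InteractionRecord]:
    """Keep records annotated with topic 'dataset' equal to ``tag`` (case-insensitive)."""
    if not tag:
        raise ConfigurationError("dataset tag must be non-empty")
    want = _norm(tag)
    return [
        r
        for r in records
        if any(
            _norm(topic) == "dataset" and _norm(value) == want
            for topic, value in r.annotations
        )
    ]


def _mutation_features(
    record: InteractionRecord, closure: frozenset[str]
) -> list[tuple[str, Feature]]:
    hits = []
    for side, feats in (("A", record.features_a), ("B", record.features_b)):
        for f in feats:
            if f.feature_type.id in closure or (
                f.feature_type.label
                and ontology.mutation_id_for_label(f.feature_type.label) in closure
            ):
                hits.append((side, f))
    return hits


def filter_mutation(
    records: list[InteractionRecord],
    closure: frozenset[str] = ontology.DEFAULT_MUTATION_CLOSURE,
) -> list[InteractionRecord]:
    """Keep records where any participant carries a mutation-branch feature."""
    ontology.validate_mutation_closure(set(closure))
    return [r for r in records if _mutation_features(r, closure)]


def filter_interaction_type(
    records: list[InteractionRecord],
    type_ids: set[str],
    include_descendants: bool = False,
    cv_table: dict[str, tuple[str, str | None]] | None = None,
) -> list[InteractionRecord]:
    """Keep records whose interaction type is in ``type_ids`` (optionally closed downward)."""
    if not type_ids:
        raise ConfigurationError("type_ids must be non-empty")
    table = cv_table if cv_table is not None else ontology.INTERACTION_TYPES
    wanted = (
        ontology.descendants(set(type_ids), table) if include_descendants else set(type_ids)
    )
    return [
        r
        for r in records
        if r.interaction_type is not None and r.interaction_type.id in wanted
    ]


def filter_host(
    records: list[InteractionRecord], host_terms: list[tuple[int, str]]
) -> list[InteractionRecord]:
    """Keep records whose host taxid matches and whose tissue text contains a pattern.

    Matching is substring-based and case-insensitive because MITAB host cells
    mix taxid with free-text tissue labels.
    """
    if not host_terms:
        raise ConfigurationError("host_terms must be non-empty")
    out = []
    for r in records:
        if r.host is None:
            continue
        text = _norm(r.host.text or "")
        for taxid, pattern in host_terms:
            if r.host.taxid == taxid and _norm(pattern) in text:
                out.append(r)
                break
    return out


def filter_taxon_pair(
    records: list[InteractionRecord], taxon_pair: tuple[int, int]
) -> list[InteractionRecord]:
    want = frozenset(taxon_pair)
    out = []
    for r in records:
        if r.taxon_a is None or r.taxon_b is None:
            continue
        if {r.taxon_a.taxid, r.taxon_b.taxid} <= want:
            out.append(r)
    return out


def filter_score(
    records: list[InteractionRecord],
    min_score: float,
    log: dict[str, int] | None = None,
) -> list[InteractionRecord]:
    """Keep records with intact-miscore >= ``min_score`` (inclusive boundary).

    Records lacking the score cannot certify high confidence and are dropped;
    their count is reported in ``log`` under ``"missing_score"`` when given.
    """
    if not (0.0 <= min_score <= 1.0):
        raise ConfigurationError(f"min_score {min_score} outside [0, 1]")
    kept, missing = [], 0
    for r in records:
        score = get_confidence(r, MISCORE_KEY)
        if score is None:
            missing += 1
        elif score >= min_score:
            kept.append(r)
    if log is not None:
        log["missing_score"] = missing
    return kept


def _validate_pattern(pattern: str) -> None:
    if not pattern:
        raise ConfigurationError("identifier pattern must be non-empty")
    if "*" in pattern[:-1]:
        raise ConfigurationError(
            f"identifier pattern {pattern!r}: wildcard only allowed at the end"
        )


def _matches_pattern(accession: str, pattern: str) -> bool:
    acc = _norm(accession)
    if pattern.endswith("*"):
        return acc.startswith(_norm(pattern[:-1]))
    return acc == _norm(pattern)


def record_identifiers(record: InteractionRecord) -> list[str]:
    ids = [record.id_a.accession, record.id_b.accession]
    ids += [i.accession for i in record.alt_ids_a]
    ids += [i.accession for i in record.alt_ids_b]
    return ids


def select_by_identifier(
    records: list[InteractionRecord], pattern: str
) -> list[InteractionRecord]:
    """Keep records where any interactor identifier matches the prefix pattern.

    ``P05067*`` matches the canonical accession, isoforms (``P05067-8``) and
    processed chains (``P05067-PRO_0000000091``); without the wildcard the
    match is exact.
    """
    _validate_pattern(pattern)
    return [
        r
        for r in records
        if any(_matches_pattern(acc, pattern) for acc in record_identifiers(r))
    ]


def classify_mutation_effect(
    record: InteractionRecord,
    closure: frozenset[str] = ontology.DEFAULT_MUTATION_CLOSURE,
) -> dict[str, list[MutationEffect]]:
    """Per-participant effect classification of the record's mutation features.

    The category comes from the feature-type CV term only (id first, label
    fallback); free text like the HGVS string is never consulted.
    """
    effects: dict[str, list[MutationEffect]] = {}
    for side, feat in _mutation_features(record, closure):
        category = ontology.effect_category(
            feat.feature_type.id, feat.feature_type.label
        )
        effects.setdefault(side, []).append(MutationEffect(category, feat))
    return effects


def effect_histogram(
    records: list[InteractionRecord],
    closure: frozenset[str] = ontology.DEFAULT_MUTATION_CLOSURE,
) -> dict[str, int]:
    """Count mutation-effect categories across all participants of all records."""
    hist: dict[str, int] = {}
    for r in records:
        for side_effects in classify_mutation_effect(r, closure).values():
            for eff in side_effects:
                hist[eff.category] = hist.get(eff.category, 0) + 1
    return hist
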