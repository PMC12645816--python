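"""Cross-variant comparison of enrichment results.

A term × network boolean presence matrix is reduced to the three classes
the comparative tables report: terms exclusive to the reference network,
terms exclusive to each comparator, and terms shared by every network.
"Detected" defaults to "appears in the enrichment report at all" — the
enrichment tables themselves contain rows above the significance cut, so
detection is membership, not significance; a significant-only criterion is
available.  Term identity is always the stable accession, never the display
name.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd

from .enrichment import EnrichmentRow, GeneSet
from .errors import AggregationError

REPORTED = "reported"
SIGNIFICANT = "significant"


@dataclass
class DifferentialReport:
    reference_label: str
    comparator_labels: list[str]
    exclusive_to_reference: set[str]
    exclusive_to_each_comparator: dict[str, set[str]]
    shared_all: set[str]
    partially_shared: set[str]
    #: terms present in the reference and absent from EVERY comparator
    #: (the table-footnote flag "not enriched in both the mutant networks")
    absent_in_all_comparators: set[str]
    matrix: pd.DataFrame = dc_field(repr=False, default=None)

    def missing_from(self, comparator: str) -> set[str]:
        """Terms detected in the reference but not in one comparator network."""
        m = self.matrix
        return set(m.index[m[self.reference_label] & ~m[comparator]])


def presence_matrix(
    enrichments: dict[str, list[EnrichmentRow]],
    criterion: str = REPORTED,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Boolean term × network matrix: True where the term passes the criterion."""
    if len(enrichments) < 2:
        raise ValueError("need at least two labeled enrichment lists")
    if criterion not in (REPORTED, SIGNIFICANT):
        raise ValueError(f"unknown criterion {criterion!r}")
    columns = {}
    term_ids: dict[str, None] = {}
    for label, rows in enrichments.items():
        present: set[str] = set()
        for row in rows:
            tid = row.term.id
            if tid in present:
                raise AggregationError(
                    f"duplicate term id {tid!r} in enrichment list {label!r}"
                )
            if criterion == REPORTED or row.term_p <= alpha:
                present.add(tid)
            term_ids.setdefault(tid, None)
        columns[label] = present
    index = sorted(term_ids)
    data = {
        label: [tid in present for tid in index]
        for label, present in columns.items()
    }
    return pd.DataFrame(data, index=pd.Index(index, name="term_id"))


def compare(matrix: pd.DataFrame, reference_label: str) -> DifferentialReport:
    """Classify terms into reference-exclusive / comparator-exclusive / shared."""
    if reference_label not in matrix.columns:
        raise ValueError(f"unknown reference label {reference_label!r}")
    comparators = [c for c in matrix.columns if c != reference_label]
    ref = matrix[reference_label]
    others = matrix[comparators]
    excl_ref = set(matrix.index[ref & ~others.any(axis=1)])
    excl_each: dict[str, set[str]] = {}
    for comp in comparators:
        rest = [c for c in matrix.columns if c != comp]
        excl_each[comp] = set(
            matrix.index[matrix[comp] & ~matrix[rest].any(axis=1)]
        )
    shared = set(matrix.index[matrix.all(axis=1)])
    classified = excl_ref | shared
    for s in excl_each.values():
        classified |= s
    partially = set(matrix.index) - classified
    return DifferentialReport(
        reference_label=reference_label,
        comparator_labels=comparators,
        exclusive_to_reference=excl_ref,
        exclusive_to_each_comparator=excl_each,
        shared_all=shared,
        partially_shared=partially,
        absent_in_all_comparators=excl_ref,
        matrix=matrix,
    )


def render_report(
    term_ids: set[str],
    geneset_metadata: dict[str, GeneSet],
    flagged: set[str] | None = None,
) -> list[tuple[str, str, str]]:
    """Rows of (accession, name, biological process), sorted by accession.

    Missing metadata renders blank (and is the caller's cue to log); process
    strings pass through verbatim.  Ids in ``flagged`` get a trailing ``*``
    (the footnote marker for terms absent from every comparator).
    """
    rows = []
    for tid in sorted(term_ids):
        gs = geneset_metadata.get(tid)
        marker = " *" if flagged and tid in flagged else ""
        rows.append(
            (
                tid + marker,
                gs.name if gs else "",
                (gs.process_annotation or "") if gs else "",
            )
        )
    return rows


def write_differential_tsv(
    report: DifferentialReport,
    geneset_metadata: dict[str, GeneSet],
    path: str | Path,
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("class\tComplex AC\tComplex name\tBiological process\n")
        sections = [
            (f"exclusive_to_{report.reference_label}", report.exclusive_to_reference),
            *(
                (f"exclusive_to_{label}", terms)
                for label, terms in sorted(report.exclusive_to_each_comparator.items())
            ),
            ("shared_all", report.shared_all),
        ]
        for section, terms in sections:
            for tid, name, process in render_report(terms, geneset_metadata):
                fh.write(f"{section}\t{tid}\t{name}\t{process}\n")


def write_presence_json(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).to_json(path, orient="index", indent=0)
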