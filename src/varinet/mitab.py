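"""PSI-MITAB 2.5/2.7 reading and writing.

The tab-delimited MITAB layout stores one binary interaction evidence per
line.  Each cell is either the empty sentinel ``-`` or a ``|``-separated list
of ``db:id(description)`` items; any of the three parts may be wrapped in
double quotes when it contains a reserved character (``|``, ``(``, ``)``,
``:``, ``"``).  The 2.7 dialect has 42 columns and adds participant
features, stoichiometry and the negative-interaction flag on top of the
15-column 2.5 core.

Accessions are treated as opaque text: isoform suffixes (``P05067-8``) and
processed-chain suffixes (``P05067-PRO_0000000091``) survive a read/write
cycle byte-identically — the downstream identifier filters rely on this.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

from .errors import MitabFormatError, MitabParseError, RecordValidationError

MITAB27_COLUMNS = 42
MITAB25_COLUMNS = 15
EMPTY = "-"

_RESERVED = set('|():"\t')

#: sentinel taxids used by curators (in vitro, chemical synthesis, ...)
_TAXID_SENTINELS = {-1, -2, -3, -4, -5}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class CvTerm:
    """A controlled-vocabulary term reference, e.g. psi-mi:"MI:0914"(association)."""

    ontology_prefix: str
    id: str
    label: str | None = None

    def __post_init__(self):
        if not self.id:
            raise RecordValidationError("CvTerm id must be non-empty")
        if self.ontology_prefix == "psi-mi":
            if not (
                self.id.startswith("MI:")
                and len(self.id) == 7
                and self.id[3:].isdigit()
            ):
                raise RecordValidationError(
                    f"psi-mi term id {self.id!r} does not match MI:dddd"
                )


@dataclass(frozen=True)
class Identifier:
    """A database cross-reference such as uniprotkb:P05067-8."""

    database: str
    accession: str
    description: str | None = None

    def __post_init__(self):
        if not self.accession:
            raise RecordValidationError("Identifier accession must be non-empty")


@dataclass(frozen=True)
class Feature:
    """A participant feature, e.g. mutation:301-301("p.Pro301Leu")."""

    feature_type: CvTerm
    range_text: str
    text: str | None = None


@dataclass(frozen=True)
class Organism:
    """An NCBI taxid plus the free-text tissue/cell-line qualifier."""

    taxid: int
    text: str | None = None

    def __post_init__(self):
        if self.taxid <= 0 and self.taxid not in _TAXID_SENTINELS:
            raise RecordValidationError(
                f"taxid must be positive or a sentinel in {sorted(_TAXID_SENTINELS)}, "
                f"got {self.taxid}"
            )


@dataclass
class InteractionRecord:
    """One parsed MITAB row (both interactors plus evidence metadata)."""

    id_a: Identifier
    id_b: Identifier
    alt_ids_a: list[Identifier] = field(default_factory=list)
    alt_ids_b: list[Identifier] = field(default_factory=list)
    aliases_a: list[Identifier] = field(default_factory=list)
    aliases_b: list[Identifier] = field(default_factory=list)
    detection_method: CvTerm | None = None
    publication_ids: list[Identifier] = field(default_factory=list)
    taxon_a: Organism | None = None
    taxon_b: Organism | None = None
    interaction_type: CvTerm | None = None
    source_db: CvTerm | None = None
    interaction_ids: list[Identifier] = field(default_factory=list)
    confidences: list[tuple[str, float]] = field(default_factory=list)
    expansion: CvTerm | None = None
    features_a: list[Feature] = field(default_factory=list)
    features_b: list[Feature] = field(default_factory=list)
    host: Organism | None = None
    annotations: list[tuple[str, str]] = field(default_factory=list)
    negative: bool = False

    def validate(self) -> None:
        if not self.interaction_ids:
            raise RecordValidationError("record has no interaction id")
        for key, value in self.confidences:
            if key == "intact-miscore" and not (0.0 <= value <= 1.0):
                raise RecordValidationError(
                    f"intact-miscore {value} outside [0, 1]"
                )


def get_confidence(record: InteractionRecord, key: str) -> float | None:
    """First confidence value stored under ``key``, or None."""
    if not key:
        raise ValueError("confidence key must be non-empty")
    for k, v in record.confidences:
        if k == key:
            return v
    return None


# ---------------------------------------------------------------------------
# cell grammar


def _split_items(text: str, line: int | None, col: int | None) -> list[str]:
    items: list[str] = []
    buf: list[str] = []
    in_quote = False
    for ch in text:
        if ch == '"':
            in_quote = not in_quote
            buf.append(ch)
        elif ch == "|" and not in_quote:
            items.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if in_quote:
        raise MitabParseError(f"unbalanced quote in cell {text!r}", line, col)
    items.append("".join(buf))
    return items


def _split_top(text: str, sep: str) -> tuple[str, str | None]:
    """Split at the first un-quoted occurrence of ``sep``."""
    in_quote = False
    for i, ch in enumerate(text):
        if ch == '"':
            in_quote = not in_quote
        elif ch == sep and not in_quote:
            return text[:i], text[i + 1:]
    return text, None


def _unquote(part: str) -> str:
    part = part.strip()
    if len(part) >= 2 and part[0] == '"' and part[-1] == '"':
        return part[1:-1]
    return part


def parse_field(
    text: str, line: int | None = None, column: int | None = None
) -> list[tuple[str, str, str | None]]:
    """Parse one MITAB cell into (db, id, description) triples.

    ``-`` yields the empty list; item order is preserved; quoted ids
    containing ``:`` or ``(`` are parsed intact.
    """
    text = text.strip()
    if text in ("", EMPTY):
        return []
    triples: list[tuple[str, str, str | None]] = []
    for item in _split_items(text, line, column):
        item = item.strip()
        if not item:
            raise MitabParseError(f"empty item in cell {text!r}", line, column)
        head, desc = _split_top(item, "(")
        description: str | None = None
        if desc is not None:
            if not desc.endswith(")"):
                raise MitabParseError(
                    f"unterminated description in item {item!r}", line, column
                )
            description = _unquote(desc[:-1])
        db, value = _split_top(head, ":")
        if value is None:
            db, value = "", db
        triples.append((_unquote(db), _unquote(value), description))
    return triples


def _quote(part: str) -> str:
    if any(c in _RESERVED for c in part):
        return f'"{part}"'
    return part


def format_field(triples: Iterable[tuple[str, str, str | None]]) -> str:
    items = []
    for db, value, desc in triples:
        item = f"{_quote(db)}:{_quote(value)}" if db else _quote(value)
        if desc is not None:
            item += f"({_quote(desc)})"
        items.append(item)
    return "|".join(items) if items else EMPTY


# ---------------------------------------------------------------------------
# cell <-> model converters


def _identifiers(cell: str, line: int, col: int) -> list[Identifier]:
    return [
        Identifier(db, acc, desc) for db, acc, desc in parse_field(cell, line, col)
    ]


def _cvterm(cell: str, line: int, col: int) -> CvTerm | None:
    triples = parse_field(cell, line, col)
    if not triples:
        return None
    db, term_id, label = triples[0]
    return CvTerm(db, term_id, label)


def _organism(cell: str, line: int, col: int) -> Organism | None:
    triples = parse_field(cell, line, col)
    if not triples:
        return None
    _, value, desc = triples[0]
    try:
        taxid = int(value)
    except ValueError as exc:
        raise MitabParseError(f"non-integer taxid {value!r}", line, col) from exc
    return Organism(taxid, desc)


def _confidences(cell: str, line: int, col: int) -> list[tuple[str, float]]:
    out = []
    for db, value, _ in parse_field(cell, line, col):
        try:
            out.append((db, float(value)))
        except ValueError as exc:
            raise MitabParseError(
                f"non-numeric confidence value {value!r} for key {db!r}", line, col
            ) from exc
    return out


def _features(cell: str, line: int, col: int) -> list[Feature]:
    feats = []
    for type_label, range_text, text in parse_field(cell, line, col):
        # Feature items are type:range(text); the type is a CV label without
        # a registered prefix, so parse_field places it in the db slot.
        from .ontology import mutation_id_for_label

        mid = mutation_id_for_label(type_label)
        term = (
            CvTerm("psi-mi", mid, type_label)
            if mid
            else CvTerm("unknown", type_label or "unspecified", type_label)
        )
        feats.append(Feature(term, range_text, text))
    return feats


def _annotations(cell: str, line: int, col: int) -> list[tuple[str, str]]:
    return [(db, value) for db, value, _ in parse_field(cell, line, col)]


def _fmt_identifiers(ids: list[Identifier]) -> str:
    return format_field((i.database, i.accession, i.description) for i in ids)


def _fmt_cvterm(term: CvTerm | None) -> str:
    if term is None:
        return EMPTY
    return format_field([(term.ontology_prefix, term.id, term.label)])


def _fmt_organism(org: Organism | None) -> str:
    if org is None:
        return EMPTY
    return format_field([("taxid", str(org.taxid), org.text)])


def _fmt_score(value: float) -> str:
    return f"{value:g}"


def _fmt_confidences(conf: list[tuple[str, float]]) -> str:
    return format_field((k, _fmt_score(v), None) for k, v in conf)


def _fmt_features(feats: list[Feature]) -> str:
    return format_field(
        (f.feature_type.label or f.feature_type.id, f.range_text, f.text)
        for f in feats
    )


def _fmt_annotations(annots: list[tuple[str, str]]) -> str:
    # annotation values are quoted by convention (they are free text)
    if not annots:
        return EMPTY
    return "|".join(f'{_quote(topic)}:"{value}"' for topic, value in annots)


# ---------------------------------------------------------------------------
# reader / writer

HEADER_27 = (
    "#ID(s) interactor A\tID(s) interactor B\tAlt. ID(s) interactor A\t"
    "Alt. ID(s) interactor B\tAlias(es) interactor A\tAlias(es) interactor B\t"
    "Interaction detection method(s)\tPublication 1st author(s)\t"
    "Publication Identifier(s)\tTaxid interactor A\tTaxid interactor B\t"
    "Interaction type(s)\tSource database(s)\tInteraction identifier(s)\t"
    "Confidence value(s)\tExpansion method(s)\tBiological role(s) interactor A\t"
    "Biological role(s) interactor B\tExperimental role(s) interactor A\t"
    "Experimental role(s) interactor B\tType(s) interactor A\tType(s) interactor B\t"
    "Xref(s) interactor A\tXref(s) interactor B\tInteraction Xref(s)\t"
    "Annotation(s) interactor A\tAnnotation(s) interactor B\t"
    "Interaction annotation(s)\tHost organism(s)\tInteraction parameter(s)\t"
    "Creation date\tUpdate date\tChecksum(s) interactor A\t"
    "Checksum(s) interactor B\tInteraction Checksum(s)\tNegative\t"
    "Feature(s) interactor A\tFeature(s) interactor B\t"
    "Stoichiometry(s) interactor A\tStoichiometry(s) interactor B\t"
    "Identification method participant A\tIdentification method participant B"
)


def _record_from_cells(cells: list[str], line_no: int) -> InteractionRecord:
    def cell(i: int) -> str:
        return cells[i] if i < len(cells) else EMPTY

    ids_a = _identifiers(cell(0), line_no, 0)
    ids_b = _identifiers(cell(1), line_no, 1)
    if not ids_a or not ids_b:
        raise MitabFormatError("missing primary interactor identifier", line_no)
    record = InteractionRecord(
        id_a=ids_a[0],
        id_b=ids_b[0],
        alt_ids_a=_identifiers(cell(2), line_no, 2),
        alt_ids_b=_identifiers(cell(3), line_no, 3),
        aliases_a=_identifiers(cell(4), line_no, 4),
        aliases_b=_identifiers(cell(5), line_no, 5),
        detection_method=_cvterm(cell(6), line_no, 6),
        publication_ids=_identifiers(cell(8), line_no, 8),
        taxon_a=_organism(cell(9), line_no, 9),
        taxon_b=_organism(cell(10), line_no, 10),
        interaction_type=_cvterm(cell(11), line_no, 11),
        source_db=_cvterm(cell(12), line_no, 12),
        interaction_ids=_identifiers(cell(13), line_no, 13),
        confidences=_confidences(cell(14), line_no, 14),
        expansion=_cvterm(cell(15), line_no, 15),
        annotations=_annotations(cell(27), line_no, 27),
        host=_organism(cell(28), line_no, 28),
        negative=cell(35).strip().lower() == "true",
        features_a=_features(cell(36), line_no, 36),
        features_b=_features(cell(37), line_no, 37),
    )
    return record


def read_mitab(
    source: str | Path | TextIO | Iterable[str], tolerant: bool = True
) -> list[InteractionRecord]:
    """Read a MITAB file into records.

    42-column lines are parsed as the 2.7 dialect.  With ``tolerant`` (the
    default) 15-column 2.5 lines are also accepted, with the feature,
    annotation and host fields left empty.  Any other column count raises
    :class:`MitabFormatError` with the line number.  Header lines start with
    ``#``; no data line is ever silently dropped.
    """
    close = False
    if isinstance(source, (str, Path)):
        stream: Iterable[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        stream = source
    records: list[InteractionRecord] = []
    try:
        for line_no, line in enumerate(stream, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) == MITAB27_COLUMNS:
                pass
            elif len(cells) == MITAB25_COLUMNS and tolerant:
                pass
            else:
                raise MitabFormatError(
                    f"expected {MITAB27_COLUMNS} (or {MITAB25_COLUMNS}) columns, "
                    f"got {len(cells)}",
                    line_no,
                )
            records.append(_record_from_cells(cells, line_no))
    finally:
        if close:
            stream.close()  # type: ignore[union-attr]
    return records


def record_to_cells(record: InteractionRecord) -> list[str]:
    record.validate()
    cells = [EMPTY] * MITAB27_COLUMNS
    cells[0] = _fmt_identifiers([record.id_a])
    cells[1] = _fmt_identifiers([record.id_b])
    cells[2] = _fmt_identifiers(record.alt_ids_a)
    cells[3] = _fmt_identifiers(record.alt_ids_b)
    cells[4] = _fmt_identifiers(record.aliases_a)
    cells[5] = _fmt_identifiers(record.aliases_b)
    cells[6] = _fmt_cvterm(record.detection_method)
    cells[8] = _fmt_identifiers(record.publication_ids)
    cells[9] = _fmt_organism(record.taxon_a)
    cells[10] = _fmt_organism(record.taxon_b)
    cells[11] = _fmt_cvterm(record.interaction_type)
    cells[12] = _fmt_cvterm(record.source_db)
    cells[13] = _fmt_identifiers(record.interaction_ids)
    cells[14] = _fmt_confidences(record.confidences)
    cells[15] = _fmt_cvterm(record.expansion)
    cells[27] = _fmt_annotations(record.annotations)
    cells[28] = _fmt_organism(record.host)
    cells[35] = "true" if record.negative else "false"
    cells[36] = _fmt_features(record.features_a)
    cells[37] = _fmt_features(record.features_b)
    return cells


def write_mitab(
    records: Iterable[InteractionRecord], dest: str | Path | TextIO
) -> None:
    """Write records as MITAB 2.7 (validating every record before output)."""
    rows = ["\t".join(record_to_cells(r)) for r in records]  # validate first
    close = False
    if isinstance(dest, (str, Path)):
        stream: TextIO = open(dest, "w", encoding="utf-8", newline="\n")
        close = True
    else:
        stream = dest
    try:
        stream.write(HEADER_27 + "\n")
        for row in rows:
            stream.write(row + "\n")
    finally:
        if close:
            stream.close()


def mitab_string(records: Iterable[InteractionRecord]) -> str:
    buf = io.StringIO()
    write_mitab(records, buf)
    return buf.getvalue()


def count_lines(source: str | Path) -> tuple[int, int, int]:
    """(total, header/blank, data) line counts — audit that nothing is dropped."""
    total = skipped = 0
    with open(source, "r", encoding="utf-8") as fh:
        for line in fh:
            total += 1
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                skipped += 1
    return total, skipped, total - skipped
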