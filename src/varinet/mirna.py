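"""miRNA causal-regulation overlay.

Causal records are signed regulatory statements (regulator, target gene,
causality phrase such as "Downregulates quantity by destabilisation") read
from a TSV in the shape curated causal-interaction resources export.  The
overlay is an exact symbol join onto a network's gene list — no identifier
mapping service is consulted.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

from .errors import MitabFormatError

#: controlled causality phrases seen in curated causal-interaction tables
KNOWN_CAUSALITY = frozenset(
    {
        "Downregulates quantity by destabilisation",
        "Downregulates quantity by repression",
        "Downregulates",
        "Upregulates",
        "Upregulates quantity by stabilisation",
        "NA",
    }
)


@dataclass(frozen=True)
class CausalRecord:
    regulator: str  # miRNA id, e.g. "hsa-mir-101-3p"
    target: str  # gene symbol
    causality: str
    source: str | None = None

    def __post_init__(self):
        if not self.regulator or not self.target:
            raise ValueError("regulator and target must be non-empty")


def load_causal(path: str | Path) -> list[CausalRecord]:
    """Read a 3+-column TSV (regulator, target, causality[, source]) with header.

    Unknown causality phrases are preserved verbatim with a warning; a row
    with fewer than 3 columns is a format error naming the line.
    """
    records = []
    with open(path, "r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        next(reader, None)  # header
        for line_no, cells in enumerate(reader, start=2):
            if not cells or (len(cells) == 1 and not cells[0].strip()):
                continue
            if len(cells) < 3:
                raise MitabFormatError(
                    f"causal table needs >= 3 columns, got {len(cells)}", line_no
                )
            causality = cells[2].strip() or "NA"
            if causality not in KNOWN_CAUSALITY:
                warnings.warn(
                    f"unknown causality phrase {causality!r} (line {line_no}); "
                    "kept verbatim",
                    stacklevel=2,
                )
            records.append(
                CausalRecord(
                    regulator=cells[0].strip(),
                    target=cells[1].strip().upper(),
                    causality=causality,
                    source=cells[3].strip() if len(cells) > 3 and cells[3].strip() else None,
                )
            )
    return records


def normalize_mirna_id(mirna: str, strip_species_prefix: bool = False) -> str:
    out = mirna.strip().lower()
    if strip_species_prefix and out.startswith("hsa-"):
        out = out[4:]
    return out


def overlay(
    causal_records: list[CausalRecord],
    genes: set[str] | list[str],
    strip_species_prefix: bool = False,
) -> dict[str, list[tuple[str, str]]]:
    """Map gene -> sorted list of (regulator, causality) for network genes.

    Exact symbol join; genes with no regulator are omitted, so every emitted
    pair exists in the causal table.
    """
    wanted = {g.upper() for g in genes}
    result: dict[str, set[tuple[str, str]]] = {}
    for rec in causal_records:
        if rec.target in wanted:
            reg = normalize_mirna_id(rec.regulator, strip_species_prefix)
            result.setdefault(rec.target, set()).add((reg, rec.causality))
    return {gene: sorted(pairs) for gene, pairs in sorted(result.items())}


def write_overlay_tsv(
    overlay_map: dict[str, list[tuple[str, str]]], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tregulator\tcausality\n")
        for gene, pairs in overlay_map.items():
            for regulator, causality in pairs:
                fh.write(f"{gene}\t{regulator}\t{causality}\n")
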