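"""Gene-set over-representation analysis with kappa-score term grouping.

The statistic is the upper-tail probability of observing at least ``k`` of a
term's ``M`` members inside a query of ``n`` genes drawn from a universe of
``N``:

* hypergeometric (Fisher's exact upper tail) — the default for complex and
  GO collections,
* binomial with success probability ``M/N`` — the convention of pathway
  browsers, offered as the pathway-mode test.

Multiple testing uses the Holm step-down procedure ("Bonferroni step down")
by default, plain Bonferroni, or the Benjamini–Hochberg step-up FDR.  Terms
whose query-hit membership vectors agree beyond chance (Cohen's kappa over
the query, threshold 0.4 by default) are merged into groups; a group is
summarised by its best member p-value and the group representatives are
corrected again across groups.

Reports mirror the conventional enrichment-table layout: term and group
p-values (raw + corrected), percent of the term covered by the query, hit
count and the sorted hit list.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field as dc_field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import networkx as nx
from scipy.stats import binom, hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

HYPERGEOMETRIC = "hypergeometric"
BINOMIAL = "binomial"

HOLM = "holm_stepdown"
BONFERRONI = "bonferroni"
BH = "benjamini_hochberg"

_SM_METHOD = {HOLM: "holm", BONFERRONI: "bonferroni", BH: "fdr_bh"}


@dataclass(frozen=True)
class GeneSet:
    """One complex/pathway definition with its stable accession."""

    id: str
    name: str
    members: frozenset[str]
    source_tag: str = ""
    process_annotation: str | None = None
    go_levels: str = "[-1]"  # pass-through metadata, never computed here

    def __post_init__(self):
        if not self.members:
            raise ConfigurationError(f"gene set {self.id} has no members")
        normalised = frozenset(m.upper() for m in self.members)
        object.__setattr__(self, "members", normalised)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class EnrichmentRow:
    term: GeneSet
    term_p: float
    term_p_corrected: float
    group_id: str
    group_p: float
    group_p_corrected: float
    percent_associated: float
    n_genes: int
    associated_genes: list[str]
    significant: bool = True


@dataclass
class EnrichmentConfig:
    test: str = HYPERGEOMETRIC
    correction: str = HOLM
    alpha: float = 0.05
    min_hits: int = 3
    kappa_threshold: float = 0.4
    universe: list[str] | None = None  # None -> union of all term members
    report_all: bool = True  # complex mode reports all rows; pathway mode filters

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ConfigurationError(f"alpha {self.alpha} outside (0, 1)")
        if self.min_hits < 1:
            raise ConfigurationError("min_hits must be >= 1")
        if self.test not in (HYPERGEOMETRIC, BINOMIAL):
            raise ConfigurationError(f"unknown test {self.test!r}")
        if self.correction not in _SM_METHOD:
            raise ConfigurationError(f"unknown correction {self.correction!r}")
        if not (-1.0 <= self.kappa_threshold <= 1.0):
            raise ConfigurationError("kappa_threshold outside [-1, 1]")


# ---------------------------------------------------------------------------
# elementary statistics


def percent_associated(k: int, M: int) -> float:
    """Coverage of a term by the query: 100*k/M, rounded half-up to 2 decimals."""
    if M < 1:
        raise ValueError("term size M must be >= 1")
    if not (0 <= k <= M):
        raise ValueError(f"hit count k={k} outside [0, M={M}]")
    return float(
        (Decimal(100 * k) / Decimal(M)).quantize(Decimal("0.01"), ROUND_HALF_UP)
    )


def term_pvalue(k: int, M: int, n: int, N: int, test: str = HYPERGEOMETRIC) -> float:
    """Upper-tail probability of >= k hits for a size-M term in an n-gene query."""
    if M > N or n > N:
        raise ValueError(f"term/query larger than universe (M={M}, n={n}, N={N})")
    if k > min(M, n) or k < 0:
        raise ValueError(f"impossible hit count k={k} for M={M}, n={n}")
    if k == 0:
        return 1.0
    if test == HYPERGEOMETRIC:
        p = float(hypergeom.sf(k - 1, N, M, n))
    elif test == BINOMIAL:
        p = float(binom.sf(k - 1, n, M / N))
    else:
        raise ConfigurationError(f"unknown test {test!r}")
    return min(1.0, max(0.0, p))


def holm_correction(pvals: list[float]) -> list[float]:
    """Holm step-down ("Bonferroni step down") adjusted p-values, input order."""
    _check_probs(pvals)
    if not pvals:
        return []
    return [float(p) for p in multipletests(pvals, method="holm")[1]]


def bonferroni_correction(pvals: list[float]) -> list[float]:
    _check_probs(pvals)
    m = len(pvals)
    return [min(1.0, m * p) for p in pvals]


def bh_fdr(pvals: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order."""
    _check_probs(pvals)
    if not pvals:
        return []
    return [float(p) for p in multipletests(pvals, method="fdr_bh")[1]]


def _check_probs(pvals: list[float]) -> None:
    for p in pvals:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")


def correct(pvals: list[float], method: str) -> list[float]:
    if method == HOLM:
        return holm_correction(pvals)
    if method == BONFERRONI:
        return bonferroni_correction(pvals)
    if method == BH:
        return bh_fdr(pvals)
    raise ConfigurationError(f"unknown correction {method!r}")


def kappa_score(set_a: set[str], set_b: set[str], domain: set[str]) -> float:
    """Cohen's kappa of two membership vectors over ``domain``.

    Identical vectors return 1.0 exactly, covering the degenerate pe = 1
    case (both sets equal to the domain or both empty).
    """
    if len(domain) < 2:
        raise ValueError("domain must contain at least 2 elements")
    if not (set_a <= domain and set_b <= domain):
        raise ValueError("sets must be subsets of the domain")
    if set_a == set_b:
        return 1.0
    t = len(domain)
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = t - a - b - c
    po = (a + d) / t
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (t * t)
    return (po - pe) / (1.0 - pe)


# ---------------------------------------------------------------------------
# grouping and the main entry point


def group_terms(
    rows: list[EnrichmentRow],
    kappa_threshold: float,
    query: set[str],
    correction: str = HOLM,
) -> list[EnrichmentRow]:
    """Assign kappa-connected-component groups and group p-values in place.

    Terms are linked when the kappa of their hit lists over the query meets
    the threshold; connected components become Group00, Group01, ... ordered
    by their best member term_p.  group_p is the smallest member term_p and
    the group representatives are corrected across groups.
    """
    if not rows:
        return rows
    g = nx.Graph()
    g.add_nodes_from(range(len(rows)))
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            kap = kappa_score(
                set(rows[i].associated_genes), set(rows[j].associated_genes), query
            )
            if kap >= kappa_threshold:
                g.add_edge(i, j)
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (min(rows[i].term_p for i in c), rows[c[0]].term.id))
    group_ps = [min(rows[i].term_p for i in comp) for comp in components]
    group_ps_corr = correct(group_ps, correction) if group_ps else []
    for gi, comp in enumerate(components):
        label = f"Group{gi:02d}"
        for i in comp:
            rows[i].group_id = label
            rows[i].group_p = group_ps[gi]
            rows[i].group_p_corrected = group_ps_corr[gi]
    return rows


def enrich(
    query_genes: list[str] | set[str],
    genesets: list[GeneSet],
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentRow]:
    """Over-representation of every gene set in the query gene list.

    Returns one row per term with at least ``min_hits`` query members,
    corrected across all tested terms, grouped by kappa, sorted by
    (group, term p, id).  A query disjoint from the universe warns and
    returns an empty list.
    """
    if config is None:
        config = EnrichmentConfig()
    if not query_genes:
        raise ValueError("query_genes must be non-empty")
    if not genesets:
        raise ValueError("genesets must be non-empty")
    if config.universe is not None:
        universe = {g.upper() for g in config.universe}
    else:
        universe = set()
        for gs in genesets:
            universe |= gs.members
    query = {g.upper() for g in query_genes} & universe
    if not query:
        warnings.warn(
            "query has no overlap with the gene-set universe; empty result",
            stacklevel=2,
        )
        return []
    n, N = len(query), len(universe)

    rows: list[EnrichmentRow] = []
    for gs in genesets:
        members = gs.members & universe
        hits = sorted(query & members)
        k, M = len(hits), len(members)
        if M == 0 or k < config.min_hits:
            continue
        p = term_pvalue(k, M, n, N, config.test)
        rows.append(
            EnrichmentRow(
                term=gs,
                term_p=p,
                term_p_corrected=p,
                group_id="Group00",
                group_p=p,
                group_p_corrected=p,
                percent_associated=percent_associated(k, M),
                n_genes=k,
                associated_genes=hits,
                significant=p <= config.alpha,
            )
        )
    if not rows:
        return rows
    corrected = correct([r.term_p for r in rows], config.correction)
    for row, cp in zip(rows, corrected):
        row.term_p_corrected = cp
    group_terms(rows, config.kappa_threshold, query, config.correction)
    if not config.report_all:
        rows = [r for r in rows if r.significant]
    rows.sort(key=lambda r: (r.group_id, r.term_p, r.term.id))
    return rows


# ---------------------------------------------------------------------------
# gene-set I/O


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read set-per-line GMT: id <tab> name/description <tab> member..."""
    sets = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise ConfigurationError(
                    f"GMT line {line_no}: expected id, name and >=1 member"
                )
            members = frozenset(c for c in cells[2:] if c)
            sets.append(GeneSet(id=cells[0], name=cells[1], members=members))
    return sets


def write_gmt(genesets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gs in genesets:
            fh.write("\t".join([gs.id, gs.name, *sorted(gs.members)]) + "\n")


def read_long_tsv(
    members_path: str | Path, metadata_path: str | Path | None = None
) -> list[GeneSet]:
    """Read a two-column (set_id, member) table plus an optional sidecar
    metadata table (id, name, source_tag, process)."""
    membership: dict[str, set[str]] = {}
    order: list[str] = []
    with open(members_path, "r", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        for cells in reader:
            if len(cells) < 2:
                continue
            set_id, member = cells[0], cells[1]
            if set_id not in membership:
                membership[set_id] = set()
                order.append(set_id)
            membership[set_id].add(member)
    meta: dict[str, tuple[str, str, str | None]] = {}
    if metadata_path is not None:
        with open(metadata_path, "r", encoding="utf-8") as fh:
            reader = csv.reader(fh, delimiter="\t")
            next(reader, None)
            for cells in reader:
                if len(cells) >= 2:
                    meta[cells[0]] = (
                        cells[1],
                        cells[2] if len(cells) > 2 else "",
                        cells[3] if len(cells) > 3 else None,
                    )
    out = []
    for set_id in order:
        name, tag, process = meta.get(set_id, (set_id, "", None))
        out.append(
            GeneSet(
                id=set_id,
                name=name,
                members=frozenset(membership[set_id]),
                source_tag=tag,
                process_annotation=process,
            )
        )
    return out


def write_set_metadata(genesets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("id\tname\tsource_tag\tprocess\n")
        for gs in genesets:
            fh.write(
                f"{gs.id}\t{gs.name}\t{gs.source_tag}\t{gs.process_annotation or ''}\n"
            )


REPORT_COLUMNS = [
    "ID",
    "Term",
    "Ontology source",
    "Term p value",
    "Term p value corrected with Bonferroni step down",
    "Group p value",
    "Group p value corrected with Bonferroni step down",
    "GOLevels",
    "GOGroups",
    "% Associated genes",
    "Nr. genes",
    "Associated genes found",
]


def write_report(rows: list[EnrichmentRow], path: str | Path) -> None:
    """Write the enrichment table with two-decimal rendering (full precision
    is retained on the in-memory rows)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.term.id,
                        r.term.name,
                        r.term.source_tag,
                        _render2(r.term_p),
                        _render2(r.term_p_corrected),
                        _render2(r.group_p),
                        _render2(r.group_p_corrected),
                        r.term.go_levels,
                        r.group_id,
                        f"{r.percent_associated:.2f}",
                        f"{float(r.n_genes):.2f}",
                        "[" + ", ".join(r.associated_genes) + "]",
                    ]
                )
                + "\n"
            )


def _render2(p: float) -> str:
    return str(Decimal(repr(p)).quantize(Decimal("0.01"), ROUND_HALF_UP))
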