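# varinet

Variant-stratified differential interactome analysis for curated
molecular-interaction corpora.

Disease mutations do not just break proteins — they rewire which partners a
protein binds, which stable macromolecular complexes it can nucleate, and
which pathways those assemblies drive. `varinet` turns that question into a
reproducible pipeline for anyone working with PSI-MITAB exports of curated
interaction datasets (e.g. a disease-focused corpus with mutation features,
tissue-annotated host organisms and `intact-miscore` confidence values):

1. **Filter** the corpus with the predicates curators expose: dataset tag,
   mutation features, interaction-type CV terms (with descendant closure),
   host-organism tissue, confidence threshold, identifier prefix
   (`P05067*` matches the canonical protein, its isoforms `P05067-8` and
   processed chains `P05067-PRO_...`).
2. **Stratify** bait interactions by the bait's sequence form: records whose
   bait participant carries a mutation feature with HGVS-like text
   (`p.Pro301Leu` → `P301L`) form that variant's stratum; clean baits form
   the reference stratum.
3. **Build** each stratum's network as the induced subgraph on its partner
   set — interactions among the partners only, never pulling in new first
   neighbours.
4. **Enrich** each partner list against complex/pathway gene sets
   (GMT or long TSV + metadata sidecar).
5. **Compare** enrichment across strata into exclusive/shared term classes.
6. **Overlay** miRNA causal regulation (regulator → target gene with a
   controlled causality phrase) onto the network genes.

## The statistics

For a query of `n` genes from a universe of `N`, a gene set with `M`
members and `k` query hits:

- **Over-representation p-value** — upper tail of the hypergeometric law
  (default; binomial with success probability `M/N` in pathway mode):

      p = Σ_{j≥k} C(M,j) · C(N−M, n−j) / C(N,n)

- **Coverage** — `% associated genes = 100·k/M`, rounded half-up to two
  decimals, as printed in enrichment tables.
- **Multiple testing** — Holm step-down ("Bonferroni step down") by
  default; plain Bonferroni and Benjamini–Hochberg FDR available.
- **Term grouping** — Cohen's kappa between the hit-membership vectors of
  two terms over the query; terms with κ ≥ 0.4 (configurable) are linked
  and connected components become `Group00, Group01, …`, each summarised by
  its best member p-value and corrected again across groups.
- **Differential report** — a boolean term × network presence matrix
  reduced to reference-exclusive, comparator-exclusive and shared-by-all
  classes ("detected" = reported at all by default, or `term_p ≤ α`).

A seed-controlled synthetic generator (`varinet.synthetic`) emits a full
benchmark bundle — MITAB 2.7 corpus, GMT complexome, causal TSV — with
planted variant-exclusive complexes, so the whole pipeline is testable
without any database download.

## Worked example

```python
from varinet import GeneSet, EnrichmentConfig, enrich

complexes = [
    GeneSet("CPX-A", "retromer-like complex", frozenset({"VPS26B", "VPS29", "VPS35"})),
    GeneSet("CPX-B", "ESCRT-like complex",
            frozenset({"CHMP1A", "CHMP4B", "CHMP5", "CHMP6", "CHMP2A", "CHMP3",
                       "CHMP7", "VPS4A", "VPS4B", "IST1", "CHMP6B", "CHMP1B"})),
    GeneSet("CPX-C", "eIF2-like complex", frozenset({"EIF2S1", "EIF2S2", "EIF2S3"})),
]
query = ["VPS26B", "VPS29", "VPS35", "CHMP1A", "CHMP4B", "CHMP5", "CHMP6"]
for row in enrich(query, complexes, EnrichmentConfig()):
    print(f"{row.term.id}  p={row.term_p:.4f}  p_holm={row.term_p_corrected:.4f}  "
          f"{row.group_id}  {row.percent_associated:.2f}%  k={row.n_genes}  {row.associated_genes}")
```

prints

```
CPX-A  p=0.0429  p_holm=0.0858  Group00  100.00%  k=3  ['VPS26B', 'VPS29', 'VPS35']
CPX-B  p=0.8835  p_holm=0.8835  Group01  33.33%  k=4  ['CHMP1A', 'CHMP4B', 'CHMP5', 'CHMP6']
```

The query covers the retromer-like complex completely (100%, k = 3 of
M = 3), which is unlikely by chance in an 18-gene universe (p = 0.043,
Holm-corrected 0.086 over the two testable terms); four of twelve ESCRT
subunits is unremarkable (p = 0.88). `CPX-C`, with zero hits, falls below
the default `min_hits = 3` gate and is not reported.

The same analysis end-to-end from the shell:

```sh
varinet synth --seed 1 --out bundle/          # synthetic corpus bundle
varinet variant-run --config run.yaml         # filter → stratify → enrich → compare
varinet query-run --mitab bundle/corpus.mitab --genesets bundle/complexes.gmt \
    --id "P10636*" --min-miscore 0.5 --out query_out/
```

Each run writes per-stratum enrichment TSVs, network edge/node lists, the
differential TSV, the miRNA overlay TSV and a `manifest.json` recording
every parameter, input digest and per-filter drop count; reruns over
unchanged inputs are bit-for-bit identical.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the synthetic bundle from the given seed, runs both workflows
(variant differential analysis and identifier-query analysis) from a cold
start, reports stratum sizes, the recovered exclusive complex sets and the
mutation-effect histogram, and writes the result map to `--out`.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
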