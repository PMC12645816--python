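# Methods

## Scope and data model

`varinet` analyses curated binary interaction evidence in PSI-MITAB format.
The 42-column 2.7 dialect is primary (it carries participant features,
host organisms, annotations and the negative flag); 15-column 2.5 files are
read in a tolerant mode with those fields empty. Cells are treated as
opaque UTF-8; Unicode hyphen variants that appear in curated free text are
normalised at comparison time only, never on disk. Isoform (`-8`) and
processed-chain (`-PRO_…`) suffixes on accessions are preserved verbatim —
the identifier-prefix filter depends on them. Negative interactions are
excluded from all downstream stages by default (a convention, not a
data-set statement; it is configurable).

Confidence is consumed, not computed: the `intact-miscore` value is read
from the confidence column and thresholded. The composite score formula
itself is out of scope. The threshold is inclusive (score ≥ cutoff, default
0.5); records lacking a score cannot certify high confidence and are
dropped, with the count reported in the filter log.

## Filters

Every filter is a pure subset operation (order-preserving, idempotent), so
profile composition is order-independent; a test asserts this algebra on
random corpora. The mutation filter matches participant features whose
type lies in a configurable closure of the mutation CV branch — the parent
term plus its effect-direction children (decreasing / increasing /
disrupting, rate and strength variants). The exact term list behind
curation platforms' "Mutation" toggle is not published, so the closure is a
package default that callers can replace. Effect classification uses the
CV term only (id first, label fallback), never the free-text HGVS string.

Host matching is substring-based on the host cell's free text plus an
exact taxid match, because MITAB host cells mix taxid and tissue labels.
Interaction-type filtering optionally closes over descendants of the
requested CV terms using a built-in ~25-term slice of the PSI-MI
vocabulary (an external OBO parser is deliberately not a dependency; the
table is replaceable by the caller).

## Stratification and networks

A record joins a variant stratum when its bait participant carries a
mutation feature whose text normalises to a short protein-change label
(three-letter residues mapped to one-letter; multi-residue
delins/del/ins/dup strings kept verbatim after stripping `p.`).
Unparsable text routes the record to an `unclassified` bucket and is never
silently dropped; prey-side mutations do not open a stratum (the variant
identity of a network is a property of the bait form) but remain available
to the effect classifier. Stratification is a partition: each record lands
in exactly one bucket.

"Network among the partners" is implemented as the induced subgraph: an
edge requires both endpoints in the partner set, so no new first
neighbours are introduced. The phrase "excluding first neighbours" in
protocol descriptions is ambiguous (it could also mean dropping degree-1
nodes); the induced-subgraph reading is the one implemented. Spoke-expanded
records are retained and flagged by default; a true-binary-only switch
drops them, which can only shrink the network. Gene symbols come from
aliases by priority gene name > gene name synonym > locus name, falling
back to the accession, and are uppercased for matching.

## Enrichment statistics

The test statistic is the upper-tail probability of at least `k` hits —
hypergeometric by default (the complex/GO convention), binomial with
success probability `M/N` in pathway mode. Both share one code path and
are checked in the tests against exact rational-arithmetic oracles and, at
small universes, literal subset enumeration. The universe defaults to the
union of all gene-set members (an explicit list is configurable); the
query is intersected with the universe before testing, and a disjoint
query warns and returns an empty result rather than raising.

"Bonferroni step down" is implemented as the Holm procedure (the standard
reading of that phrase), with plain Bonferroni and Benjamini–Hochberg as
alternatives; the implementations are thin wrappers over
`statsmodels.stats.multitest`, cross-checked against hand-coded
step-down/step-up recursions. `min_hits` defaults to 3 — published
complex-enrichment tables rarely report terms below three associated
genes. Percent coverage is rounded half-up to two decimals for report
parity; full precision is kept internally.

Grouping follows the kappa-clustering convention: Cohen's kappa between
two terms' hit-membership vectors over the query, an edge at κ ≥ 0.4 (the
documented default of the reference tool), connected components as groups
ordered by best member p-value. The group statistic of the reference tool
is not published; the group p-value here is the minimum member term p,
with Holm applied across group representatives. Identical membership
vectors define κ = 1 even when the expected agreement is 1 (the degenerate
case is resolved to perfect agreement).

Complex-mode reports keep all rows with a significance flag, because
published complex tables contain rows above α while the comparative
narrative still speaks of "detection"; pathway mode filters at term_p ≤ α,
matching the pathway-browser protocol. The differential "detected"
criterion is correspondingly "reported at all" by default with a
significant-only mode available — the published text does not disambiguate
between the two, so both are first-class.

## Synthetic benchmark

The generator's defaults are the stated world of the acceptance tests:
universe of 500 genes, 40 complexes with sizes uniform on [3, 15], three
strata (reference, P301L, V337M) with 80 bait records each, two planted
exclusive complexes per stratum, scores Beta(5, 2) rounded to two decimals
(bounded, mass near the 0.5 threshold), host tissues drawn from
{hippocampus, cerebral cortex, neuron}, dataset tag `alzheimers`, 30% of
background records carrying prey-side direction-bearing mutation features,
10% colocalisation-typed, 5% negative and 20% spoke-expanded background
records, and 60 prey–prey evidence rows for network induction.

Three construction choices make planted-signal recovery a property of the
pipeline rather than of sampling luck, and they are what a green
recovery test does and does not establish:

* complexes are disjoint by default (`overlap_rate = 0`), so a planted
  complex cannot leak partial coverage into another stratum through shared
  membership;
* background preys (and their scores, types, tissues and flags) are shared
  across strata — the same underlying evidence feeds every stratum — so
  background coverage is identical across networks and only planted
  complexes can differ; budget beyond the shared core becomes replicate
  evidence for already-covered preys, never new coverage;
* planted-complex scores are resampled to land strictly above the
  threshold.

A green planted-recovery run therefore establishes that filtering,
stratification, enrichment and comparison compose correctly; it does not
establish robustness to overlapping complexes or stratum-specific
background, which real corpora have. The generator exposes `overlap_rate`
and per-stratum budgets for such stress tests, but the differential report
is then no longer guaranteed to equal the planted truth.

With `mutation_fraction = 0` a reference-only corpus contains no mutation
features at all; in multi-variant configurations the variant baits carry
their defining mutation features regardless, since stratification depends
on them.

The default variant-workflow filter profile does not require a mutation
feature on every record: in the protocol being reproduced the mutation
filter is part of corpus retrieval, and the reference stratum is defined
by the absence of a bait-variant feature. `require_mutation` remains an
ordinary profile option.

## Null calibration

The exact upper-tail test is discrete and therefore conservative: for the
default complexome the attainable rejection rate at α = 0.05 under a
uniform random query is ≈ 0.02–0.026 for any query size between 25 and
200 (computed analytically from the hypergeometric tail mass). The test
suite checks two things: (a) the pooled empirical rejection fraction over
200 independent replicates (query size 75, fixed a priori) lies within the
95% binomial interval around the nominal level taken over the replicate
count; and (b) more sharply, that the empirical fraction matches the exact
analytic tail-mass expectation within binomial bounds. Readers should not
expect the empirical type-I error of a discrete exact test to equal α.

## Numerical conventions

* p-values are clipped to [0, 1]; `k = 0` returns exactly 1.0.
* Percent coverage uses decimal half-up rounding (not banker's rounding).
* Group labels are zero-padded (`Group00`) and assigned in order of best
  member p-value with term-accession tie-breaks, making reports
  deterministic.
* Scores are serialised with `%g`, which round-trips the two-decimal
  canonical corpora byte-identically; arbitrary-precision floats are not
  guaranteed byte-stable through MITAB serialisation.
* All randomness flows from a single integer seed through
  `numpy.random.default_rng`; generator sub-streams use fixed offsets
  (seed, seed+1, seed+2) so the complexome, corpus and causal table are
  independently reproducible.

## Known limitations

* PSI-MI XML, live database queries and the full query-language grammar
  (boolean nesting, arbitrary field qualifiers) are out of scope.
* GO DAG levels are pass-through metadata; no ontology hierarchy is
  computed.
* The controlled-vocabulary slice covers only the interaction-type and
  mutation branches the filters consult.
* The miRNA overlay is an exact symbol join; no identifier mapping across
  namespaces is attempted.
* Statistical comparison between enrichment lists is set comparison only;
  no test of differential enrichment magnitude is performed.
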