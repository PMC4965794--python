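# Methods

## The annotation model

The package treats eQTL evidence as the medium between variants and
function. Three relations are composed:

1. **SNP → gene** (eQTL): association tables with a SNP rsID, a gene
   symbol and an FDR/q-value, read through a caller-supplied column map
   because public eQTL resources ship heterogeneous layouts. The
   inclusion filter keeps records with FDR strictly below the
   threshold (default 0.05; an FDR exactly at the threshold is
   excluded) whose SNP id matches the reference-SNP pattern `rs\d+`.
   Builds are tissue-stratified: each table carries a tissue label, and
   merging tissues is an explicit operation because the union changes
   the enrichment universe.
2. **gene → GO term** (annotation): GAF 2.x files, gene identity taken
   from the gene-symbol column, `NOT`-qualified rows excluded, ND
   ("unknown") evidence rows excluded always, any other evidence kept
   unless a filter is given. Gene symbols are matched case-sensitively.
3. **term → ancestor** (ontology): the GO DAG from an OBO file,
   restricted to non-obsolete terms and to `is_a`/`part_of` edges
   (the `regulates` family is excluded by default, the standard choice
   for enrichment; the edge set is configurable). `alt_id`s resolve to
   their canonical term. The true-path rule — a gene annotated to a
   term is annotated to all its ancestors — is applied by an explicit,
   idempotent `propagate()` step, on by default but switchable, so
   analyses with direct-only annotations are equally reproducible.

A SNP and a term are associated iff they share at least one gene after
these relations are composed. Each association record keeps its full
provenance — the exact set of mediating genes (which is provably the
intersection of the SNP's eQTL genes with the term's annotated genes)
and the tissues it arose in. Duplicate (SNP, term) pairs are merged by
unioning provenance. All exports are canonically ordered (SNP, then
term id); nothing in the build is randomised.

## The enrichment test

Let `N` be the number of SNPs in the build's universe (SNPs with ≥ 1
association), `M` the number of query SNPs inside that universe
(query SNPs outside it carry no annotation, are dropped from `M` and
reported once per run), `n` the universe SNPs annotated to a term and
`m` the query SNPs among them. The p-value is the one-sided
hypergeometric upper tail P(X ≥ m) — the Fisher exact test for
over-representation. Only the upper tail is offered as the default
reading; enrichment, not depletion, is the quantity of interest in
this design.

Numerics: the tail is summed in log space (log-gamma binomial
coefficients combined with `logsumexp`), so universes of hundreds of
thousands of SNPs are handled without overflow; the result is clipped
into (0, 1] and `m` at the lower support edge returns exactly 1.0.
Tests verify agreement with literal draw enumeration and exact
rational arithmetic to 1e-10 across every valid configuration with
N ≤ 25, and with `scipy.stats.hypergeom.sf` at larger sizes.

The tested family is the set of terms the query touches (m ≥ 1); this
matches the convention of reporting "the k terms the query is
annotated in". A switch widens the family to every term in the build,
which changes the adjustment denominator — the choice is recorded in
the run metadata. Results are sorted by ascending p with the term id
as a deterministic tie-break.

### Multiple-testing adjustments

All seven procedures are implemented from first principles with the
same semantics as R's `p.adjust`, and cross-checked in tests against
`statsmodels` and a brute-force closed-testing oracle:

- `bonferroni`: k·p, clipped at 1.
- `holm`: step-down, cumulative maximum of (k−i+1)·p₍ᵢ₎.
- `hochberg`: step-up mirror, cumulative minimum from the largest rank.
- `hommel`: closed testing with Simes local tests, via the usual
  O(k²) recursion; verified against explicit enumeration of all
  2ᵏ−1 subsets for small k.
- `BH` (alias `fdr`, the default): step-up with factors k/i.
- `BY`: BH inflated by the harmonic sum Σ 1/j.
- `none`: identity.

Adjusted values are always in [p, 1], and the conservativeness
ordering bonferroni ≥ holm ≥ hochberg ≥ hommel and BY ≥ BH holds
pointwise. The default significance threshold is adjusted p < 0.01,
with 0.05 available via `--alpha`.

## Position baseline and comparison

The baseline assigns a SNP to every gene whose body (plus an optional
symmetric flank, default 0 bp — the most conservative rule, recorded
in run metadata) contains its position; intervals are 0-based
half-open everywhere (GFF input is shifted on read), strand is
ignored. The positional (SNP, gene) pairs then flow through *the same*
join and enrichment code path as the eQTL pairs — the two methods
differ only in the SNP→gene step and in their universes. The
comparison report intersects the significant term sets of two runs at
a chosen threshold (recomputed from the stored adjusted p-values, by
term identity only) and breaks shared/exclusive sets down by
BP/CC/MF, with proportions reported to one decimal percent.

## Synthetic data

The generator emits, from one integer seed, byte-identical bundles:
a GO-like DAG (default 25 terms: the three namespace roots and
non-root terms with one or two same-namespace parents), 60 genes of
which 5 stay unannotated (to exercise the coverage report), direct
annotations of 3–8 genes per non-root term written as GAF, an eQTL
table for 200 SNPs with on average 2 linked genes each, gene bodies in
non-overlapping 30 kb slots on three chromosomes, and SNP loci placed
mostly inside an eQTL-linked gene (cis), sometimes in a random gene or
intergenic, so the positional and eQTL maps correlate without
coinciding. True eQTL links draw FDR uniformly below 0.05 and decoy
links (20%) above it, so the inclusion filter is exercised exactly; a
handful of rows carry positional SNP names to exercise the rsID
filter. One BP leaf term, a direct child of the BP root with 8
dedicated genes, is the planted term; its ancestors are deliberately
broad so the planted leaf, not a parent, carries the sharpest signal.

Queries are drawn without replacement from the build universe with
inclusion odds ρ for SNPs annotated to the planted term (ρ = 1 is a
uniform null draw). Sizes were chosen so that the whole suite runs in
seconds while the planted signal at ρ = 20, query size 30 is
overwhelming (the planted term ranks first with BH-adjusted p < 0.01
in 100/100 query draws on the default bundle).

What the generator does **not** emulate: linkage disequilibrium
between SNPs, allele-frequency structure, tissue sharing of real
eQTLs, or the scale-free degree structure of the real GO. Passing
tests therefore demonstrate the correctness of the pipeline's logic
and statistics under its own model assumptions, not performance on
real GWAS data — in particular, the absence of LD makes SNP-level
independence assumptions exact here that are violated in practice.

## Calibration of the discrete test

The exact hypergeometric test is discrete: for each term only a finite
set of p-values is attainable, so the probability of p < 0.05 under a
uniform null is at most 0.05 and typically below it. On the default
bundle the expected fraction of tested null-term results with raw
p < 0.05, computed analytically term by term, is ≈ 0.034, and
simulation over 200 uniform queries reproduces this to Monte-Carlo
error. This conservativeness is a property of exact tests at these
counts, not an implementation artifact; a mid-p variant would trade it
for inflated size and is deliberately not offered.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GFF is converted on
  read (start − 1). A single convention removes off-by-one risk in the
  overlap rule `g.start − w ≤ pos < g.end + w`.
- Strict parsing is the default: a malformed row aborts with its line
  number. Lenient mode skips and reports rows, preserving
  `rows_in = rows_out + skips`.
- Ties in enrichment output are broken by term id; all file outputs
  are canonically sorted, so identical inputs yield identical bytes.
- Config resolution is CLI flag > config file > default, and every
  command serialises its resolved configuration plus SHA-256 hashes of
  its inputs next to its outputs.
- Degenerate inputs: an empty filtered eQTL table yields an empty
  build (allowed, logged); enrichment on an empty build or with a
  query disjoint from the universe is an error; a query equal to the
  universe yields p = 1 for every term.

## Known limitations

- Gene identity is by case-sensitive symbol; no synonym resolution is
  attempted unless the caller maps symbols beforehand.
- No LD-aware or permutation null (SNPs in LD inflate `m` jointly);
  terms tested are treated as independent families per run.
- The position baseline offers no nearest-gene fallback or regulatory
  annotation — gene-body (± flank) overlap only.
- Real-scale databases (hundreds of thousands of SNPs) are supported
  by the log-space numerics but all shipped examples are small
  synthetic bundles.
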