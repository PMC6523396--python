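# Methods

## Problem setting

Closely related inbred strains — the parents used in crop breeding
programs — are hard to genotype with pre-designed marker arrays because of
ascertainment bias in the source polymorphisms. Calling variants directly
from RNA-Seq sidesteps the bias and targets genic sequence, but the reads
are low-coverage and expression-dependent, so the raw calls need aggressive
reliability filtering before they are usable as markers. `transgeno`
implements that downstream path: target-region construction, the filter
cascade, panel analytics, and two agreement-based quality checks. Upstream
steps (read trimming, splice-aware alignment, transcript assembly, variant
calling itself) are out of scope; the input is a merged multi-sample VCF
with per-sample `GT` and `DP` (or `AD`) fields.

## Transcribed regions

A gene locus is its full genomic span (exons plus introns). Each locus is
extended by `flank_bp` (default 3,000 bp) on **both** sides regardless of
strand: "upstream/downstream" has no well-defined strand rule for
strand-unknown novel loci, so symmetric flanks are the only consistent
choice. Extensions are clipped at position 0 and at the chromosome length
when a length table is supplied. Overlapping **and book-ended** (touching)
intervals merge into one region carrying all member locus ids; merging
touching spans yields the canonical minimal region set and is idempotent
and order-invariant (both properties are tested against an independent
per-base boolean-mask union oracle). All internal coordinates are 0-based
half-open; GFF3 (1-based closed) is converted at the parser and BED output
needs no conversion. `RegionStats.ratio_vs_reference` is the bp total of a
region set over a reference set's total, rendered to two decimals.

## Filter cascade

Stage order is fixed — depth → singleton → conflict → multi-allele →
neighbor — and each stage operates on the previous stage's survivors, which
makes the stage counts monotone non-increasing (tested). Conventions:

* **Detected**: a VCF row is a detected polymorphism when at least one
  strain's selected library carries a non-reference allele; rows
  homozygous-reference (or missing) everywhere never enter the cascade.
* **Depth** (`min_reads = 2`): a failing call becomes missing; the site is
  not removed wholesale. "Depth" is the per-sample total read depth (`DP`),
  or the sum of allele depths when only `AD` is present. A toggle
  (`min_reads_hets_only`) restricts the rule to heterozygous calls, since
  the rationale is strongest there (one read can never show both alleles).
* **Singleton**: evaluated on one call per strain (see library selection);
  fails when fewer than two strains carry a non-reference allele among
  non-missing calls, which also removes monomorphic leftovers created by
  depth masking.
* **Conflict**: fails when any strain with ≥2 libraries has two unequal
  non-missing genotype calls at the site. This reads the replicate-
  inconsistency rule as *within-strain* disagreement; `drop_conflicts`
  switches it off for users who prefer a different reading.
* **Multi-allele**: sites with ≥2 ALT alleles are tallied (`n_multi`) and
  excluded from the marker panel by default — a marker assay interrogates
  one substitution.
* **Neighbor** (`neighbor_window = 60` bp): a site survives only if no
  other surviving candidate lies within the window on the same chromosome;
  **both** members of a too-close pair are dropped. The boundary is
  inclusive (distance exactly 60 removes; 61 keeps); `neighbor_inclusive =
  False` selects the strict-inequality alternative. Distance is measured
  between VCF `POS` fields of left-normalized records; indel spans are not
  expanded. The single sorted sweep is sufficient because any violation
  implies one with an adjacent site; it is tested against an all-pairs
  oracle on random site sets. The filter runs after multi-allele exclusion,
  so an excluded locus cannot shadow a good marker.

**Library selection.** When a strain has several libraries, one is chosen
deterministically for genotyping: the first library whose tissue tag
matches the preference list (default `("shoot_root",)`, the tissue common
to all strains in the motivating design), with lexicographic tie-breaks.
All libraries still participate in the conflict rule.

## Matrix analytics

* **Pairwise differences**: for each unordered strain pair, count sites
  where both calls are non-missing and the genotype strings differ
  (het-vs-hom is a difference), split by SNP/indel. Missing-vs-anything is
  never a difference, so missingness cannot inflate distances. The table is
  symmetric with a zero diagonal (tested, plus a brute-force oracle).
* **Group filter**: restricted to the strains of one group (here barley
  row type), a site is kept when MAF ≥ 0.1 **and** missing fraction < 0.5.
  MAF is allele-count based — a homozygote contributes two copies, a
  heterozygote one of each — and the minor allele is the second most
  frequent. With inbred material hets are rare, but the convention is fixed
  so results are reproducible. The filter is idempotent.
* **Gap scan**: a gap is an interval between *adjacent* markers whose
  1-based position difference strictly exceeds `min_len` (default 1 Mbp);
  the length convention (plain difference, endpoints exclusive) is pinned
  by the worked example in the tests: flanking markers 97,779,576 and
  400,251,595 give 302,472,019 bp. Chromosome-end gaps are excluded unless
  a chromosome-length table is passed, since the flanking-marker definition
  does not apply there.

## Concordance

* **Replicate agreement**: sites called in both libraries are agreed or
  disagreed; sites called in exactly one are reported separately and
  excluded from `rate = 100·agreed/(agreed+disagreed)`. With no shared
  sites the rate is undefined (`None`), never 0 or 100.
* **Depth gate**: amplicon markers with mean depth below 100× are removed
  before comparison ("below" is strict; exactly 100 is retained).
* **Per-strain comparison**: per gated marker, a missing call on *either*
  platform counts as not-detected (excluded from rates); otherwise
  normalized genotype equality decides true vs false, stratified by the
  marker's SNP/indel class. Rates are percentages rounded **half-up** to
  three decimals; the summary means are rendered at one decimal.
* **Summary**: the per-class summary rates are the *mean of per-strain
  rates* (pooled-count rates are emitted alongside as an alternative), and
  the threshold count uses `rate_total ≥ threshold` — the inclusive
  comparison is the one consistent with a strain printing exactly 90.000
  being counted among the high-agreement strains.
* **Genotype normalization**: allele order is canonicalized and, for
  genotypes with two distinct alleles, bases shared by both alleles are
  trimmed (suffix first, then prefix, keeping one anchor base) so that
  platform-specific indel padding such as `ATCC/AC` vs `ATC/A` compares
  equal. Homozygous genotypes are never trimmed — a lone allele string has
  no internal contrast, and trimming it would collapse homozygous indels
  onto the reference. Cross-platform padding differences of *homozygous*
  indel calls are therefore not reconciled; both platforms must emit the
  same representation, which the fixture generator guarantees.
* **Per-marker aggregation** reports raw counts plus *both* percentage
  conventions (complete matches over all markers, and over markers with
  complete data) without asserting either as canonical.

## Synthetic data generator

The generator emulates the statistical structure of a ~100-strain inbred
RNA-Seq genotyping study at desk scale; defaults: 2 chromosomes × 400 kbp,
60 loci of 4 kbp, 12 strains of which 4 have a second (replicate) library,
40 clean markers, 10 singletons, 6 close pairs (40 bp spacing), 4
multi-allelic loci, indel fraction 0.2. Strains are fully inbred (true
genotypes homozygous); `het_rate` (0.02) injects heterozygous calls as
library-level noise. Per-call depths are negative-binomial (mean 20, shape
4) — an overdispersed proxy for expression-dependent RNA-Seq coverage —
and calls go missing at `missing_rate` (0.08). Replicate libraries copy the
primary library's calls and flip 9% of them (`replicate_discordance_rate`,
matching a ~91% replicate agreement regime); the amplicon platform flips
7% and drops 30% of calls, and 11/384 of panel markers are forced below
the 100× depth gate.

Planted sites sit on a 200-bp grid inside loci (margin 100 bp), so
non-pair sites are always farther apart than the 60-bp window while
close-pair partners (40 bp) always violate it. Two carriers per
clean/close-pair site (one for singletons) are *protected* — never masked,
never het, depth ≥ 2 — so each planted site remains detectable and its
category label stays truthful under noise. Consequences worth knowing:
with noise enabled, replicate flips can kill a clean marker at the
conflict stage, and a close-pair member whose partner died earlier can
survive the neighbor filter — both are realistic cascade behaviours, which
is why exact panel recovery is asserted only for the noise-free
configuration (`SimConfig.noise_free()`). All randomness derives from
`SimConfig.seed` through per-component substreams; a fixed seed reproduces
every output file byte-for-byte.

What the generator does **not** emulate: linkage disequilibrium and
population structure, expression correlation along chromosomes, alignment
and calling artefacts (reads are never simulated), multi-nucleotide and
complex variants. Passing recovery tests therefore demonstrate the
correctness of the filtering and accounting logic, not calling accuracy on
real RNA-Seq data.

## Problem sizes and numerical choices

The test suite and acceptance script run simulations at the default toy
scale, plus one larger layout (2 × 700 kbp, 2,600 clean markers, two
libraries, 5% planted discordance) chosen so the replicate comparison
shares more than 2,000 sites — enough for a 95% binomial-interval check of
the recovered discordance rate. Rounding of printed rates uses decimal
half-up (never float banker's rounding); rate denominators of zero yield
`None` rather than a sentinel number; thousands separators appear only in
rendered tables, never in TSV/JSON outputs; and the run report contains no
timestamps so reruns are byte-identical.

## Known limitations

* The neighbor rule, MAF and missingness boundaries are inclusive/strict
  in the directions documented above; datasets produced by other tools may
  have used the opposite conventions, which the config toggles cover.
* The conflict rule interprets "different calls from multiple strains" as
  within-strain replicate conflict; a cross-strain reading would be a
  different filter.
* Indel comparison assumes both call sets use left-normalized
  representations; no reference-aware realignment is performed.
* `run_cascade` holds the detected polymorphic sites in memory; this is
  appropriate for transcribed-region-restricted call sets, not
  whole-genome ones.
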