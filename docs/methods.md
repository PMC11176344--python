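# Methods

## The screen

The package implements a three-stage heuristic for nominating
expansion-prone CNG trinucleotide repeat loci:

1. **Detection.** Every maximal run of contiguous, *exact* copies of
   each query motif in a reference genome, with at least `min_units`
   copies. Interrupted or impure repeats are out of scope by design:
   the screen targets pure runs because purity is the strongest known
   correlate of expansion propensity, and exact matching keeps the
   detection definition unambiguous and testable against a brute-force
   oracle.
2. **Annotation and prioritization.** One functional region label per
   locus from a transcript model, then the candidate rule: at least 10
   units in the reference and an exonic location (CDS or UTR), where
   nearly all known pathogenic CNG expansions reside.
3. **Population variability.** Candidates genotyped in a control cohort
   are summarized per locus; loci whose allele-length span reaches the
   polymorphism threshold are the proposed expansion-prone set, and
   cohorts/populations are compared nonparametrically.

## Detection details

* A run is *maximal* when neither flank continues with one further full
  motif copy. Motifs must be primitive (a periodic unit such as CAGCAG
  is rejected); maximal runs of a primitive motif cannot overlap, so
  greedy leftmost regex matching enumerates them exactly. The
  brute-force oracle used in the tests checks every (start, motif) pair
  against the definition directly and is kept independent of the regex
  path.
* Each motif is scanned independently. A CCG run of n units contains a
  frame-shifted GCC run of n − 1 units; both are reported by default
  because the downstream count matrix tallies the units separately.
  `dedup_frame_shifts` suppresses any locus wholly contained in a
  strictly longer locus of a rotation-equivalent motif, for analyses
  that want one locus per physical repeat tract.
* N (or any non-ACGT character rejected at validation) never matches;
  with `break_on_ambiguous` (default) the flanking runs are evaluated
  independently against `min_units`. Setting it false instead treats N
  as a wildcard — useful for scanning draft sequence.
* Soft-masked lowercase sequence is scanned by default
  (`case_sensitive=False`): repeat tracts are largely inside masked
  regions, and a screen that skipped them would miss most of its
  targets.
* Coordinates are 0-based half-open internally; writers also emit
  1-based inclusive columns, the convention of most published locus
  tables.

## Annotation details

* Per transcript: CDS overlap → Coding; overlap with the first
  `splice_window` (default 2) intronic bases at an internal exon
  boundary → Splicing, or Exonic;Splicing when the locus also overlaps
  an exon; UTR overlap is strand-aware (5'/3' derived from the CDS
  position in the exon chain); inside the span with no exon overlap →
  Intronic; noncoding transcripts give ncRNA-Exonic/ncRNA-Intronic; a
  gap of less than `upstream_window` (default 1000 bp, 0 = adjacent)
  from the strand-aware start/end → Upstream/Downstream.
* Across transcripts, candidate labels resolve by fixed precedence
  (Exonic;Splicing > Coding > Splicing > 5'UTR;3'UTR > 5'UTR > 3'UTR >
  ncRNA-Exonic > Intronic > ncRNA-Intronic > Upstream/Downstream >
  Upstream > Downstream > Intergenic); Upstream of one transcript plus
  Downstream of another promotes to Upstream/Downstream. Ties among
  transcripts carrying the winning label break on (gene, transcript id)
  so results are independent of input order. The window defaults are
  the conventional choices of offline gene-based annotators; both are
  configurable because published screens rarely pin them.
* Overlap means ≥ 1 shared base throughout. The windows measure the gap
  in bases between nearest bases, so "gap < window" is the membership
  rule; adjacency is gap 0.

## Prioritization

Reference-length groups: 4–6, 7–9, ≥ 10 units. The candidate region set
includes the combined exonic labels (Exonic;Splicing, 5'UTR;3'UTR) by
default since they are exonic locations too; `PURE_CANDIDATE_REGIONS`
restricts to the three pure labels. The length rule defaults to ≥ 10
(consistent with candidate tables whose reference length is exactly
10); the threshold is a parameter for screens that prefer > 10. The
count-matrix writer always recomputes row totals from cells, so the
conservation invariant (row totals = cell sums; grand total = locus
count) cannot be violated by a stale column.

## Genotype statistics

* Fragment conversion: units = round((fragment − flank) / unit_len);
  residuals > 1 bp are logged, as off-grid peaks usually indicate a
  mis-specified flank.
* Statistics are computed over the diploid allele multiset (two alleles
  per genotyped sample), so "number of chromosomes" is twice the sample
  count; samples that failed genotyping are simply absent, which is why
  chromosome counts differ across loci. SD is the sample standard
  deviation (n − 1); mode ties break toward the smaller allele; the
  median of an even multiset is the mean of the central pair.
* HI is *observed* heterozygosity (share of heterozygous individuals).
  Expected heterozygosity 1 − Σpᵢ² from the sample allele frequencies
  is reported in a separate, clearly named column; under random mating
  the two converge, and the simulation tests exploit exactly that.
* Stability: span = max − min allele length; span ≥ 7 units →
  polymorphic. The rule is open-ended above the threshold. A per-locus
  override list can force loci polymorphic, provided for reproducing
  published call sets that flag a locus falling just under the rule
  (the packaged screen's RAI1, span 6, is the one such case — its
  published call disagrees with its printed range, and the override
  restores the published set verbatim).
* Cohort comparison: rank-sum compares the two allele multisets at one
  locus; signed-rank pairs per-locus modal lengths across the shared
  loci of two cohorts (the pairing unit is the locus — with summary
  tables rather than raw genotypes per population, the locus is the
  only available pairing). The exact null distribution is used when the
  smaller side has ≤ 25 observations and there are no ties; otherwise
  the midrank normal approximation with tie and continuity corrections.
  Zero rank variance (identical values throughout) returns p = 1. The
  method actually used is logged and recorded in the output.

## Synthetic data

* `make_genome` plants specified runs into uniform ACGT background and
  then *repairs*: the finished genome is scanned, and any background
  bases participating in a run not contained in a planted span are
  re-drawn, iterating to convergence. This guarantees the truth table
  is exhaustive — essential for exact precision/recall tests — and
  keeps planted runs maximal. Frame-shift echoes of planted runs by
  rotation-equivalent motifs are physically unavoidable and appear in
  the truth table flagged `planted=False`.
* `make_gene_model` builds one compact transcript construct per planted
  locus realizing its requested label (reaching at most 1500 bp away,
  so loci must sit ≥ 5 kb apart). The combined 5'UTR;3'UTR label is
  rejected as unsatisfiable: a contiguous locus touching both UTRs of
  one transcript would have to cross the CDS between them.
* `make_cohort` draws two alleles per sample per locus independently
  from the specified spectrum (Hardy–Weinberg random mating) and emits
  the expected heterozygosity per locus.
* What the generators do **not** emulate: sequencing or PCR artifacts
  (stutter, allele dropout), impure/interrupted repeats, linkage
  between loci, population structure, or mutation dynamics across
  generations. Passing tests therefore demonstrate algorithmic
  correctness on clean inputs, not robustness to real assay noise.

## Problem sizes and seeds

The shipped test fixtures use two chromosomes of ~40–50 kb with 13
planted loci covering every satisfiable region label, cohorts of up to
2000 samples for heterozygosity calibration (tolerance three binomial
standard errors), and 100 seeded replicate pairs of 200-sample cohorts
for the rank-sum type-I-error check (per-replicate streams spawned from
one master seed; the test's measured size is ~1% at nominal α = 0.01).
All generators take explicit seeds and are bit-reproducible; the
pipeline manifest omits wall-clock time unless `--stamp` is passed so
that identical runs are byte-identical.

## Known limitations

* Exact-copy detection only; a single interruption splits a tract.
* Region labels depend on the transcript snapshot supplied; candidate
  lists are only as reproducible as the gene model they were built on.
* The annotator reports one winning gene/transcript per locus; loci in
  dense loci clusters may legitimately belong to several genes.
* The signed-rank comparison on summary tables uses modal lengths only;
  full allele distributions per external population, when available,
  are better served by the rank-sum mode on expanded catalogs.
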