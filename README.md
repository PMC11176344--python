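# cng-screen

Genome-wide screening of unstable **CNG trinucleotide repeat** loci.

Expansions of CNG repeats (CAG, CCG, CGG, CTG, GCC) cause a large share
of inherited neurodegenerative disease — the spinocerebellar ataxias,
Huntington disease, myotonic dystrophy and others. Finding *new*
expansion-prone loci by long-read sequencing of patient cohorts is
expensive; a cheaper heuristic is to (1) enumerate every exact CNG
repeat run in the reference genome, (2) keep the long, exonic ones, and
(3) measure their length variability in a genotyped control population:
loci that are already highly polymorphic in healthy carriers are the
best candidates for pathogenic expansion. This package implements that
screen end to end, for geneticists who want to reproduce, re-run, or
adapt it.

## What it computes

* **Scanner** — every *maximal run* of ≥ `min_units` (default 4)
  contiguous exact copies of each motif, per FASTA record. A run is
  maximal when it cannot be extended by one full copy on either side.
  Ambiguity (N) breaks runs; soft-masked sequence is scanned by default;
  frame-shifted runs of rotation-equivalent motifs (CCG ⊃ GCC) are
  reported independently unless `--dedup-frames` is set.
* **Annotator** — exactly one region label per locus from a 13-category
  vocabulary (Coding, Splicing, Exonic;Splicing, 5'UTR, 3'UTR,
  5'UTR;3'UTR, Intronic, ncRNA-Exonic, ncRNA-Intronic, Upstream,
  Downstream, Upstream/Downstream, Intergenic), resolved across
  transcripts by a fixed precedence order. GFF3 and refGene-style TSV
  gene models are both accepted.
* **Prioritizer** — length groups (Group 1: 4–6, Group 2: 7–9,
  Group 3: ≥ 10 units), a (group × unit) × region count matrix, and the
  candidate rule *n_units ≥ 10 and label ∈ {CDS, UTR}*.
* **Genotype statistics** — fragment-size → repeat-unit conversion
  (units = round((fragment − flank)/unit_len)); per-locus allele
  statistics over the diploid allele multiset (range, mode, mean,
  sample SD, median, allele counts); the heterozygosity index
  HI = #heterozygous samples / #samples (expected heterozygosity
  1 − Σpᵢ² is reported alongside); stability classification by the
  variability span (max − min ≥ 7 units → polymorphic); and Wilcoxon
  rank-sum / signed-rank cohort comparisons (exact null for small
  tie-free samples, midrank normal approximation with continuity
  correction otherwise).
* **Synthetic generators** — seeded genomes with planted repeat runs
  (background repaired until the truth table is provably exhaustive),
  gene models realizing requested region labels, and diploid cohorts
  drawn from known allele spectra under Hardy–Weinberg random mating.

It also ships small reference tables transcribed from the published
hg19 screen it re-implements (15 × group/unit locus totals summing to
15,069; the 52 exonic candidates with control ranges; the 19
polymorphic loci's cohort statistics; 1000 Genomes superpopulation
mode/ranges) for desk-scale consistency checks — see
`cng_screen.catalog`.

## Worked example

Simulate a small genome with four planted repeat runs, then run the
screen:

```bash
cat > fixture.yaml <<'EOF'
chrom_lengths: {chr1: 30000}
plants:
  - {chrom: chr1, position: 6000, unit: CAG, n_units: 12, label: Coding}
  - {chrom: chr1, position: 12000, unit: CTG, n_units: 11, label: "5'UTR"}
  - {chrom: chr1, position: 18000, unit: CGG, n_units: 10, label: Intronic}
  - {chrom: chr1, position: 24000, unit: CAG, n_units: 5, label: Coding}
EOF
cng-screen simulate genome --spec fixture.yaml --seed 17 --out sim
cng-screen simulate genes  --spec fixture.yaml --seed 17 --out sim
cng-screen scan --fasta sim/genome.fa --out loci.tsv
cng-screen annotate --loci loci.tsv --genes sim/genes.gff3 --out annotated.tsv
cng-screen prioritize --annotated annotated.tsv --min-units 10 \
    --out candidates.tsv --matrix matrix.tsv
```

which prints `4 loci written to loci.tsv`, then
`2 candidate loci written to candidates.tsv`, and leaves

```
gene    transcript  chrom  start1  end1   unit  label  n_units
SG001   SG001.t1    chr1   6001    6036   CAG   Coding 12
SG002   SG002.t1    chr1   12001   12033  CTG   5'UTR  11
```

in `candidates.tsv`: of the four planted runs, the 10-unit intronic CGG
run fails the region rule and the 5-unit CAG run fails the length rule,
so exactly the two long exonic runs survive — the screen's selection
logic in miniature. `loci.tsv` carries both 0-based half-open
(`start0`/`end0`) and 1-based inclusive (`start1`/`end1`) coordinates.

The same stages run from one config via `cng-screen run --config
run.yaml --out-dir out/`, which also writes a `manifest.json` with
input checksums and per-file row counts; re-running with the same seed
and inputs is byte-identical. Cohort statistics:
`cng-screen genotype-stats`, `classify`, `compare`.

## Layout

```
src/cng_screen/
  scanner.py     maximal exact tandem-repeat detection (+ brute-force oracle)
  annotate.py    transcript models, region labels, precedence resolution
  prioritize.py  length groups, count matrix, candidate selection
  genotype.py    allele statistics, stability, Wilcoxon comparisons, catalogs
  simulate.py    seeded genome / gene-model / cohort generators with truth
  catalog.py     packaged reference tables of the published screen
  pipeline.py    staged driver with atomic outputs and a run manifest
  cli.py         the cng-screen command
docs/methods.md  model, parameters, and design notes
```
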