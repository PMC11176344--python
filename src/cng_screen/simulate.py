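"""Seeded synthetic genomes, gene models and diploid cohorts with known truth.

Every pipeline stage is testable offline against fixtures whose correct
answer is known by construction:

* :func:`make_genome` plants pure repeat runs of chosen motif, position
  and unit count into random background sequence, then *repairs* the
  background (re-drawing any bases that form accidental runs of a
  configured motif, or that extend a planted run) until the scanner's
  output over the whole genome is exactly the set of runs implied by
  the planted specs. The returned truth table is therefore exhaustive.
* :func:`make_gene_model` builds coding and noncoding transcripts that
  place each planted locus into a requested region (CDS, UTR, intron,
  splice boundary, ncRNA exon, near-gene window, or nowhere), emitting
  the expected label, gene and transcript per locus.
* :func:`make_cohort` draws diploid genotypes from per-locus
  allele-frequency spectra under random mating (Hardy-Weinberg),
  emitting the expected heterozygosity 1 - sum p_i^2 per locus.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import RegionLabel, Transcript
from .genotype import AlleleCall, CohortTable, expected_heterozygosity
from .scanner import RepeatLocus, RepeatMotif, ScanConfig, scan_sequence

_BASES = np.array(list("ACGT"))

#: Half-width of the widest transcript construct around a planted locus
#: (near-gene transcripts reach 1500 bp away, plus the 1000 bp window).
_INFLUENCE = 2500


@dataclass(frozen=True)
class PlantSpec:
    """One repeat run to plant, with the region label expected after annotation."""

    chrom: str
    position: int  # 0-based start
    unit: str
    n_units: int
    label_truth: RegionLabel | None = None
    strand: str = "+"

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit", RepeatMotif(self.unit).unit)
        if self.position < 0:
            raise ValueError("position must be >= 0")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")

    @property
    def start(self) -> int:
        return self.position

    @property
    def end(self) -> int:
        return self.position + self.n_units * len(self.unit)


@dataclass(frozen=True)
class SpectrumSpec:
    """Allele-frequency spectrum of one locus (repeat units -> probability)."""

    locus: str
    allele_units: tuple[int, ...]
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        alleles = tuple(int(a) for a in self.allele_units)
        freqs = tuple(float(f) for f in self.freqs)
        if len(alleles) != len(freqs) or not alleles:
            raise ValueError("allele_units and freqs must be equal-length, non-empty")
        if len(set(alleles)) != len(alleles):
            raise ValueError("alleles must be distinct")
        if any(f < 0 for f in freqs):
            raise ValueError("freqs must be >= 0")
        if not math.isclose(sum(freqs), 1.0, abs_tol=1e-9):
            raise ValueError(f"freqs sum to {sum(freqs)}, expected 1")
        object.__setattr__(self, "allele_units", alleles)
        object.__setattr__(self, "freqs", freqs)

    @property
    def expected_het(self) -> float:
        return expected_heterozygosity(self.freqs)


def _validate_plants(
    specs: Sequence[PlantSpec], chrom_lengths: Mapping[str, int]
) -> None:
    by_chrom: dict[str, list[PlantSpec]] = {}
    for s in specs:
        if s.chrom not in chrom_lengths:
            raise ValueError(f"planted chrom {s.chrom!r} not in chrom_lengths")
        if s.end > chrom_lengths[s.chrom]:
            raise ValueError(f"plant at {s.chrom}:{s.start} exceeds chromosome length")
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda s: s.start)
        for left, right in zip(group, group[1:]):
            gap = right.start - left.end
            min_gap = 2 * max(len(left.unit), len(right.unit))
            if gap < min_gap:
                raise ValueError(
                    f"planted runs on {chrom} overlap or are closer than "
                    f"{min_gap} bp (gap {gap})"
                )


def make_genome(
    specs: Sequence[PlantSpec],
    chrom_lengths: Mapping[str, int],
    seed: int,
    config: ScanConfig | None = None,
    max_repair_rounds: int = 1000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with planted repeat runs and an exhaustive truth table.

    Background bases are uniform over ACGT; any window that accidentally
    forms a reportable run of a configured motif — or extends a planted
    run — is re-drawn until the scan of the finished genome contains
    only runs inside planted spans. The truth table is that final scan;
    runs matching a spec exactly are flagged ``planted=True``, and
    frame-shifted echoes of a planted run by a rotation-equivalent
    configured motif (a planted CCG run contains a GCC run) appear with
    ``planted=False``.
    """
    config = config or ScanConfig.default()
    _validate_plants(specs, chrom_lengths)
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    planted_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_lengths}
    planted_mask: dict[str, np.ndarray] = {}
    for chrom, length in chrom_lengths.items():
        arrays[chrom] = _BASES[rng.integers(0, 4, size=length)]
        planted_mask[chrom] = np.zeros(length, dtype=bool)
    for s in specs:
        run = np.array(list(s.unit * s.n_units))
        arrays[s.chrom][s.start:s.end] = run
        planted_mask[s.chrom][s.start:s.end] = True
        planted_spans[s.chrom].append((s.start, s.end))

    scan_cfg = ScanConfig(
        motifs=config.motifs,
        min_units=config.min_units,
        case_sensitive=config.case_sensitive,
        break_on_ambiguous=config.break_on_ambiguous,
        dedup_frame_shifts=False,
    )
    for _ in range(max_repair_rounds):
        offenders = 0
        for chrom, arr in arrays.items():
            seq = "".join(arr)
            spans = planted_spans[chrom]
            redraw = np.zeros(arr.size, dtype=bool)
            for locus in scan_sequence(seq, chrom, scan_cfg):
                inside = any(ps <= locus.start and locus.end <= pe for ps, pe in spans)
                if not inside:
                    redraw[locus.start:locus.end] = True
            redraw &= ~planted_mask[chrom]
            if redraw.any():
                offenders += int(redraw.sum())
                arr[redraw] = _BASES[rng.integers(0, 4, size=int(redraw.sum()))]
        if offenders == 0:
            break
    else:
        raise RuntimeError("genome repair did not converge; loosen the motif set")

    records = {chrom: "".join(arr) for chrom, arr in arrays.items()}
    spec_keys = {(s.chrom, s.start, s.end, s.unit) for s in specs}
    rows = []
    for chrom, seq in records.items():
        for locus in scan_sequence(seq, chrom, config):
            rows.append(
                {
                    "chrom": chrom,
                    "start0": locus.start,
                    "end0": locus.end,
                    "unit": locus.unit.unit,
                    "n_units": locus.n_units,
                    "planted": (chrom, locus.start, locus.end, locus.unit.unit)
                    in spec_keys,
                }
            )
    truth = pd.DataFrame(
        rows, columns=["chrom", "start0", "end0", "unit", "n_units", "planted"]
    )
    return records, truth


def write_genome_fasta(
    records: Mapping[str, str], path: str | Path, width: int = 60
) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _updown_expectation(gene_a: str, tx_a: str, gene_b: str, tx_b: str) -> tuple[str, str]:
    near = sorted({(gene_a, tx_a), (gene_b, tx_b)})
    return ";".join(sorted({g for g, _ in near})), ";".join(t for _, t in near)


def make_gene_model(
    specs: Sequence[PlantSpec], seed: int = 0
) -> tuple[list[Transcript], pd.DataFrame]:
    """Transcripts realizing each planted locus's requested region label.

    Constructs are deterministic geometry around each locus (the seed
    only fixes the API with the other generators); the widest reaches
    1500 bp from the locus, so planted loci on one chromosome must be
    at least 5 kb apart to keep their constructs independent.
    The combined 5'UTR;3'UTR label is unsatisfiable for a contiguous
    locus (it would have to cross the CDS separating the two UTRs) and
    is rejected.
    """
    del seed
    ordered = sorted(specs, key=lambda s: (s.chrom, s.position))
    for left, right in zip(ordered, ordered[1:]):
        if left.chrom == right.chrom and right.start - left.end < 2 * _INFLUENCE:
            raise ValueError(
                f"planted loci on {left.chrom} closer than {2 * _INFLUENCE} bp; "
                "their gene constructs would interfere"
            )
    transcripts: list[Transcript] = []
    rows = []
    for i, s in enumerate(ordered, start=1):
        a, b = s.start, s.end
        st = s.strand
        gene, tx = f"SG{i:03d}", f"SG{i:03d}.t1"
        label = s.label_truth
        exp_gene, exp_tx = gene, tx
        if label is None or label is RegionLabel.INTERGENIC:
            label = RegionLabel.INTERGENIC
            exp_gene, exp_tx = "", ""
        elif label is RegionLabel.UTR5_UTR3:
            raise ValueError(
                "5'UTR;3'UTR is unsatisfiable for a contiguous locus in one transcript"
            )
        elif label is RegionLabel.CODING:
            transcripts.append(
                Transcript(tx, gene, s.chrom, st, ((a - 60, b + 60),), a - 30, b + 30)
            )
        elif label in (RegionLabel.UTR5, RegionLabel.UTR3):
            five = (label is RegionLabel.UTR5) == (st == "+")
            if five:  # locus left of the CDS on the genome
                transcripts.append(
                    Transcript(tx, gene, s.chrom, st, ((a - 60, b + 120),),
                               b + 30, b + 90)
                )
            else:
                transcripts.append(
                    Transcript(tx, gene, s.chrom, st, ((a - 120, b + 60),),
                               a - 90, a - 30)
                )
        elif label is RegionLabel.INTRONIC:
            transcripts.append(
                Transcript(tx, gene, s.chrom, st,
                           ((a - 200, a - 100), (b + 100, b + 200)), a - 150, b + 150)
            )
        elif label is RegionLabel.SPLICING:
            transcripts.append(
                Transcript(tx, gene, s.chrom, st,
                           ((a - 100, a - 1), (b + 100, b + 200)), a - 50, b + 150)
            )
        elif label is RegionLabel.EXONIC_SPLICING:
            k = len(s.unit)
            transcripts.append(
                Transcript(tx, gene, s.chrom, st,
                           ((a - 100, a + k), (b + 100, b + 200)), a - 50, b + 150)
            )
        elif label is RegionLabel.NCRNA_EXONIC:
            transcripts.append(Transcript(tx, gene, s.chrom, st, ((a - 60, b + 60),)))
        elif label is RegionLabel.NCRNA_INTRONIC:
            transcripts.append(
                Transcript(tx, gene, s.chrom, st,
                           ((a - 200, a - 100), (b + 100, b + 200)))
            )
        elif label in (RegionLabel.UPSTREAM, RegionLabel.DOWNSTREAM):
            before = (label is RegionLabel.UPSTREAM) == (st == "+")
            if before:  # transcript begins after the locus on the genome
                exons = ((b + 500, b + 1500),)
                cds = (b + 600, b + 1400)
            else:
                exons = ((a - 1500, a - 500),)
                cds = (a - 1400, a - 600)
            transcripts.append(Transcript(tx, gene, s.chrom, st, exons, *cds))
        elif label is RegionLabel.UP_DOWN:
            gene_a, tx_a = f"SG{i:03d}A", f"SG{i:03d}A.t1"
            gene_b, tx_b = f"SG{i:03d}B", f"SG{i:03d}B.t1"
            transcripts.append(
                Transcript(tx_a, gene_a, s.chrom, "+",
                           ((a - 1500, a - 500),), a - 1400, a - 600)
            )
            transcripts.append(
                Transcript(tx_b, gene_b, s.chrom, "+",
                           ((b + 500, b + 1500),), b + 600, b + 1400)
            )
            exp_gene, exp_tx = _updown_expectation(gene_a, tx_a, gene_b, tx_b)
        else:
            raise ValueError(f"unsupported truth label {label}")
        rows.append(
            {
                "chrom": s.chrom, "start0": a, "end0": b, "unit": s.unit,
                "n_units": s.n_units, "label": label.value,
                "gene": exp_gene, "transcript": exp_tx,
            }
        )
    truth = pd.DataFrame(
        rows,
        columns=["chrom", "start0", "end0", "unit", "n_units", "label", "gene",
                 "transcript"],
    )
    return transcripts, truth


def make_cohort(
    spectra: Sequence[SpectrumSpec],
    n_samples: int,
    seed: int,
    cohort: str = "controls",
) -> tuple[CohortTable, pd.DataFrame]:
    """Diploid cohort drawn from per-locus spectra under random mating."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    calls = []
    for i in range(1, n_samples + 1):
        sample = f"S{i:04d}"
        for spec in spectra:
            a1, a2 = rng.choice(spec.allele_units, size=2, p=spec.freqs)
            calls.append(AlleleCall(sample, spec.locus, int(a1), int(a2)))
    truth = pd.DataFrame(
        [
            {"locus": s.locus, "expected_het": s.expected_het,
             "alleles": ",".join(map(str, s.allele_units)),
             "freqs": ",".join(f"{f:g}" for f in s.freqs)}
            for s in spectra
        ],
        columns=["locus", "expected_het", "alleles", "freqs"],
    )
    return CohortTable(cohort, tuple(calls)), truth


def write_cohort_tsv(table: CohortTable, path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("sample\tcohort\tlocus\ta1_units\ta2_units\n")
        for c in table.calls:
            fh.write(f"{c.sample}\t{table.cohort}\t{c.locus}\t{c.a1}\t{c.a2}\n")
            n += 1
    return n
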