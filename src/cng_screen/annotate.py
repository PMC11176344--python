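"""Gene-based functional region annotation of repeat loci.

Each locus receives exactly one region label from a fixed 13-category
vocabulary (Coding, Splicing, UTRs, intronic, ncRNA, near-gene,
intergenic). Per transcript, a candidate label is derived from overlap
with CDS, UTR and exon intervals and proximity to splice boundaries or
the transcript ends; across transcripts, candidates are resolved by a
fixed precedence order, so adding transcripts can only move a label
upward in precedence. Both GFF3 (1-based inclusive) and refGene-style
TSV (0-based half-open) gene models are accepted and normalized to the
internal 0-based half-open convention.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .scanner import RepeatLocus

log = logging.getLogger(__name__)


class RegionLabel(str, Enum):
    CODING = "Coding"
    SPLICING = "Splicing"
    EXONIC_SPLICING = "Exonic;Splicing"
    UTR5 = "5'UTR"
    UTR3 = "3'UTR"
    UTR5_UTR3 = "5'UTR;3'UTR"
    INTRONIC = "Intronic"
    NCRNA_EXONIC = "ncRNA-Exonic"
    NCRNA_INTRONIC = "ncRNA-Intronic"
    UPSTREAM = "Upstream"
    DOWNSTREAM = "Downstream"
    UP_DOWN = "Upstream/Downstream"
    INTERGENIC = "Intergenic"


#: Cross-transcript conflict resolution, highest priority first.
PRECEDENCE: tuple[RegionLabel, ...] = (
    RegionLabel.EXONIC_SPLICING,
    RegionLabel.CODING,
    RegionLabel.SPLICING,
    RegionLabel.UTR5_UTR3,
    RegionLabel.UTR5,
    RegionLabel.UTR3,
    RegionLabel.NCRNA_EXONIC,
    RegionLabel.INTRONIC,
    RegionLabel.NCRNA_INTRONIC,
    RegionLabel.UP_DOWN,
    RegionLabel.UPSTREAM,
    RegionLabel.DOWNSTREAM,
    RegionLabel.INTERGENIC,
)

_RANK = {label: i for i, label in enumerate(PRECEDENCE)}


@dataclass(frozen=True)
class Transcript:
    """A transcript model: ordered exons plus an optional CDS interval.

    All coordinates are 0-based half-open. ``cds_start``/``cds_end`` are
    None for noncoding transcripts; for coding transcripts the CDS
    interval must lie within the exon span. UTR intervals are derived
    strand-aware from the exon structure and CDS position.
    """

    id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(tuple(e) for e in self.exons)
        if not exons:
            raise ValueError(f"transcript {self.id}: no exons")
        for s, e in exons:
            if s >= e or s < 0:
                raise ValueError(f"transcript {self.id}: invalid exon [{s}, {e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"transcript {self.id}: exons overlap or are unsorted")
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"transcript {self.id}: partial CDS interval")
        if self.cds_start is not None:
            if not (exons[0][0] <= self.cds_start < self.cds_end <= exons[-1][1]):
                raise ValueError(
                    f"transcript {self.id}: CDS [{self.cds_start}, {self.cds_end}) "
                    "outside exon span"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def coding(self) -> bool:
        return self.cds_start is not None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def cds_intervals(self) -> list[tuple[int, int]]:
        if not self.coding:
            return []
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    def utr_intervals(self) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
        """(5'UTR, 3'UTR) exonic intervals, strand-aware."""
        if not self.coding:
            return [], []
        left, right = [], []
        for s, e in self.exons:
            if s < self.cds_start:
                left.append((s, min(e, self.cds_start)))
            if e > self.cds_end:
                right.append((max(s, self.cds_end), e))
        return (left, right) if self.strand == "+" else (right, left)

    def intron_intervals(self) -> list[tuple[int, int]]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if e1 < s2
        ]


@dataclass
class GeneModel:
    """A set of transcripts plus the near-gene and splice windows (bp)."""

    transcripts: tuple[Transcript, ...]
    upstream_window: int = 1000
    splice_window: int = 2

    def __post_init__(self) -> None:
        self.transcripts = tuple(self.transcripts)
        if not self.transcripts:
            raise ValueError("gene model must contain at least one transcript")
        if self.upstream_window < 0 or self.splice_window < 0:
            raise ValueError("windows must be >= 0")


@dataclass(frozen=True)
class AnnotatedLocus:
    """A repeat locus with its single resolved region label."""

    locus: RepeatLocus
    label: RegionLabel
    gene: str = ""
    transcript: str = ""

    def __post_init__(self) -> None:
        if (self.gene == "") != (self.label is RegionLabel.INTERGENIC):
            raise ValueError(
                f"gene must be empty iff label is Intergenic (got {self.gene!r}, "
                f"{self.label.value})"
            )


def _overlaps(ls: int, le: int, s: int, e: int) -> bool:
    return ls < e and le > s


def classify_against_transcript(
    locus: RepeatLocus,
    t: Transcript,
    upstream_window: int = 1000,
    splice_window: int = 2,
) -> RegionLabel | None:
    """The single label the locus earns from one transcript, or None.

    Overlap is >=1 shared base. Splicing means overlap with the first
    ``splice_window`` intronic bases at an internal exon boundary;
    combined with any exon overlap it becomes Exonic;Splicing.
    Near-gene (Upstream/Downstream) is strand-aware with a gap of less
    than ``upstream_window`` bases (0 = adjacent) and applies only when
    the locus does not overlap the transcript span.
    """
    if locus.chrom != t.chrom:
        return None
    ls, le = locus.start, locus.end
    if _overlaps(ls, le, t.start, t.end):
        exon_ov = any(_overlaps(ls, le, s, e) for s, e in t.exons)
        splice = False
        for i_s, i_e in t.intron_intervals():
            donor = (i_s, min(i_s + splice_window, i_e))
            acceptor = (max(i_e - splice_window, i_s), i_e)
            if _overlaps(ls, le, *donor) or _overlaps(ls, le, *acceptor):
                splice = True
                break
        if not t.coding:
            return RegionLabel.NCRNA_EXONIC if exon_ov else RegionLabel.NCRNA_INTRONIC
        if splice and exon_ov:
            return RegionLabel.EXONIC_SPLICING
        if any(_overlaps(ls, le, s, e) for s, e in t.cds_intervals()):
            return RegionLabel.CODING
        if splice:
            return RegionLabel.SPLICING
        utr5, utr3 = t.utr_intervals()
        in5 = any(_overlaps(ls, le, s, e) for s, e in utr5)
        in3 = any(_overlaps(ls, le, s, e) for s, e in utr3)
        if in5 and in3:
            return RegionLabel.UTR5_UTR3
        if in5:
            return RegionLabel.UTR5
        if in3:
            return RegionLabel.UTR3
        return RegionLabel.INTRONIC
    if t.strand == "+":
        upstream = (t.start - upstream_window, t.start)
        downstream = (t.end, t.end + upstream_window)
    else:
        upstream = (t.end, t.end + upstream_window)
        downstream = (t.start - upstream_window, t.start)
    if upstream[0] < upstream[1] and _overlaps(ls, le, *upstream):
        return RegionLabel.UPSTREAM
    if downstream[0] < downstream[1] and _overlaps(ls, le, *downstream):
        return RegionLabel.DOWNSTREAM
    return None


def annotate(
    loci: Iterable[RepeatLocus],
    model: GeneModel,
    on_unknown_chrom: str = "warn",
) -> list[AnnotatedLocus]:
    """Resolve one region label per locus across all transcripts.

    Candidate labels from every overlapping or nearby transcript are
    reduced by :data:`PRECEDENCE`; a locus Upstream of one transcript
    and Downstream of another is promoted to Upstream/Downstream. Ties
    between transcripts carrying the winning label break on
    (gene, transcript id) for order-independence. Loci on chromosomes
    absent from the model are Intergenic (``on_unknown_chrom="reject"``
    raises instead).
    """
    if on_unknown_chrom not in {"warn", "reject"}:
        raise ValueError("on_unknown_chrom must be 'warn' or 'reject'")
    pad = model.upstream_window
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for t in model.transcripts:
        trees[t.chrom].addi(t.start - pad, t.end + pad, t)
    warned: set[str] = set()
    out: list[AnnotatedLocus] = []
    for locus in loci:
        if locus.chrom not in trees:
            if on_unknown_chrom == "reject":
                raise ValueError(f"locus chromosome {locus.chrom!r} not in gene model")
            if locus.chrom not in warned:
                log.warning(
                    "chromosome %s absent from gene model; labeling Intergenic",
                    locus.chrom,
                )
                warned.add(locus.chrom)
            out.append(AnnotatedLocus(locus, RegionLabel.INTERGENIC))
            continue
        cands: list[tuple[RegionLabel, Transcript]] = []
        for iv in trees[locus.chrom].overlap(locus.start, locus.end):
            label = classify_against_transcript(
                locus, iv.data, model.upstream_window, model.splice_window
            )
            if label is not None:
                cands.append((label, iv.data))
        if not cands:
            out.append(AnnotatedLocus(locus, RegionLabel.INTERGENIC))
            continue
        labels = {label for label, _ in cands}
        best = min(labels, key=_RANK.__getitem__)
        if best in (RegionLabel.UPSTREAM, RegionLabel.DOWNSTREAM) and {
            RegionLabel.UPSTREAM,
            RegionLabel.DOWNSTREAM,
        } <= labels:
            near = sorted(
                {(t.gene, t.id) for label, t in cands
                 if label in (RegionLabel.UPSTREAM, RegionLabel.DOWNSTREAM)}
            )
            out.append(
                AnnotatedLocus(
                    locus,
                    RegionLabel.UP_DOWN,
                    ";".join(sorted({g for g, _ in near})),
                    ";".join(i for _, i in near),
                )
            )
            continue
        winner = min(
            (t for label, t in cands if label is best), key=lambda t: (t.gene, t.id)
        )
        out.append(AnnotatedLocus(locus, best, winner.gene, winner.id))
    return out


# ---------------------------------------------------------------------------
# Gene-model readers / writers

REFGENE_COLUMNS = (
    "name", "chrom", "strand", "txStart", "txEnd", "cdsStart", "cdsEnd",
    "exonCount", "exonStarts", "exonEnds", "gene",
)


def read_refgene(path: str | Path) -> list[Transcript]:
    """Read a refGene-style TSV (0-based half-open starts, UCSC convention).

    A header line naming the columns is optional; without one the
    canonical column order is assumed. ``cdsStart == cdsEnd`` marks a
    noncoding transcript.
    """
    log.info("reading gene model %s as refGene-style TSV (0-based half-open)", path)
    transcripts = []
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ValueError(f"empty gene model file: {path}")
        cols = first.lstrip("#").rstrip("\n").split("\t")
        if cols[0] == "name":
            idx = {c: i for i, c in enumerate(cols)}
            lines = fh
        else:
            idx = {c: i for i, c in enumerate(REFGENE_COLUMNS)}
            lines = [first] + list(fh)
        for line in lines:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            starts = [int(x) for x in f[idx["exonStarts"]].rstrip(",").split(",")]
            ends = [int(x) for x in f[idx["exonEnds"]].rstrip(",").split(",")]
            if len(starts) != int(f[idx["exonCount"]]) or len(starts) != len(ends):
                raise ValueError(f"exon count mismatch for {f[idx['name']]}")
            cds_s, cds_e = int(f[idx["cdsStart"]]), int(f[idx["cdsEnd"]])
            coding = cds_s < cds_e
            transcripts.append(
                Transcript(
                    id=f[idx["name"]],
                    gene=f[idx["gene"]],
                    chrom=f[idx["chrom"]],
                    strand=f[idx["strand"]],
                    exons=tuple(zip(starts, ends)),
                    cds_start=cds_s if coding else None,
                    cds_end=cds_e if coding else None,
                )
            )
    return transcripts


_NONCODING_TYPES = {
    "transcript", "ncRNA", "lnc_RNA", "snoRNA", "snRNA", "miRNA", "tRNA", "rRNA",
    "pseudogenic_transcript",
}


def read_gff3(path: str | Path) -> list[Transcript]:
    """Read transcripts from GFF3 (1-based inclusive; normalized internally).

    Any feature owning exon children is treated as a transcript; it is
    coding iff it owns CDS children. The gene symbol comes from a
    ``gene`` attribute on the transcript, else the parent gene's Name.
    """
    import gffutils

    log.info("reading gene model %s as GFF3 (1-based inclusive)", path)
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    transcripts = []
    for feat in db.all_features():
        if feat.featuretype in {"gene", "exon", "CDS"}:
            continue
        exons = sorted(
            (e.start - 1, e.end) for e in db.children(feat, featuretype="exon")
        )
        if not exons:
            continue
        cds = sorted((c.start - 1, c.end) for c in db.children(feat, featuretype="CDS"))
        gene = feat.attributes.get("gene", [None])[0]
        if gene is None:
            parents = list(db.parents(feat, featuretype="gene"))
            gene = (
                parents[0].attributes.get("Name", [parents[0].id])[0]
                if parents
                else feat.id
            )
        transcripts.append(
            Transcript(
                id=feat.id,
                gene=gene,
                chrom=feat.seqid,
                strand=feat.strand if feat.strand in "+-" else "+",
                exons=tuple(exons),
                cds_start=cds[0][0] if cds else None,
                cds_end=cds[-1][1] if cds else None,
            )
        )
    return transcripts


def read_gene_model(
    path: str | Path, upstream_window: int = 1000, splice_window: int = 2
) -> GeneModel:
    """Load a gene model, detecting GFF3 vs refGene-style TSV by extension."""
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        transcripts = read_gff3(path)
    else:
        transcripts = read_refgene(path)
    return GeneModel(tuple(transcripts), upstream_window, splice_window)


def write_gff3(transcripts: Sequence[Transcript], path: str | Path) -> None:
    """Write transcripts as GFF3 (coding as mRNA + CDS, noncoding as transcript)."""
    by_gene: dict[tuple[str, str], list[Transcript]] = defaultdict(list)
    for t in transcripts:
        by_gene[(t.chrom, t.gene)].append(t)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for (chrom, gene), txs in sorted(by_gene.items()):
            g_start = min(t.start for t in txs)
            g_end = max(t.end for t in txs)
            fh.write(
                f"{chrom}\tcng-screen\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{txs[0].strand}\t.\tID=gene:{gene};Name={gene}\n"
            )
            for t in sorted(txs, key=lambda t: t.id):
                ftype = "mRNA" if t.coding else "transcript"
                fh.write(
                    f"{t.chrom}\tcng-screen\t{ftype}\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\tID={t.id};Parent=gene:{gene};gene={gene}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\tcng-screen\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t"
                        f"Parent={t.id}\n"
                    )
                for s, e in t.cds_intervals():
                    fh.write(
                        f"{t.chrom}\tcng-screen\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0\t"
                        f"Parent={t.id}\n"
                    )


ANNOTATED_TSV_HEADER = (
    "chrom", "start0", "end0", "unit", "n_units", "label", "gene", "transcript",
)


def write_annotated_tsv(annotated: Iterable[AnnotatedLocus], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(ANNOTATED_TSV_HEADER) + "\n")
        for a in annotated:
            locus = a.locus
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.unit.unit}\t"
                f"{locus.n_units}\t{a.label.value}\t{a.gene}\t{a.transcript}\n"
            )
            n += 1
    return n


def read_annotated_tsv(path: str | Path) -> list[AnnotatedLocus]:
    from .scanner import RepeatMotif

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            motif = RepeatMotif(f[idx["unit"]])
            n = int(f[idx["n_units"]])
            locus = RepeatLocus(
                f[idx["chrom"]], int(f[idx["start0"]]), int(f[idx["end0"]]),
                motif, n, motif.unit * n,
            )
            out.append(
                AnnotatedLocus(
                    locus, RegionLabel(f[idx["label"]]), f[idx["gene"]],
                    f[idx["transcript"]],
                )
            )
    return out
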