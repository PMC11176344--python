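"""Maximal exact tandem-repeat detection in DNA sequence.

The scanner reports every *maximal run* of contiguous, exact copies of a
set of query motifs — by default the CNG trinucleotides CAG, CCG, CGG,
CTG and GCC, the repeat class behind most expansion disorders of the
nervous system. A run is maximal when it cannot be extended by one
further full motif copy on either side. Each motif is scanned
independently, so rotationally equivalent motifs (a CCG run contains a
frame-shifted GCC run) may report overlapping loci; an optional dedup
pass suppresses any locus wholly contained in a longer locus of a
rotation-equivalent motif.

Coordinates are 0-based half-open internally; the TSV writer also emits
1-based inclusive columns.
"""

from __future__ import annotations

import gzip
import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

log = logging.getLogger(__name__)

#: Default CNG repeat units screened genome-wide.
DEFAULT_UNITS: tuple[str, ...] = ("CAG", "CCG", "CGG", "CTG", "GCC")

#: Upper bound on sequence length accepted by :func:`brute_force_oracle`.
ORACLE_MAX_LEN = 10_000

_DNA = frozenset("ACGT")
_INVALID = re.compile(r"[^ACGTNacgtn]")


def _smallest_period(unit: str) -> int:
    for p in range(1, len(unit)):
        if len(unit) % p == 0 and unit == unit[:p] * (len(unit) // p):
            return p
    return len(unit)


@dataclass(frozen=True, order=True)
class RepeatMotif:
    """A repeat unit to scan for, e.g. ``RepeatMotif("CAG")``.

    Units are upper-cased on construction and must be primitive
    (``"CAGCAG"`` is rejected: counting its copies is ill-defined
    relative to its primitive unit ``"CAG"``).
    """

    unit: str
    label: str = ""

    def __post_init__(self) -> None:
        unit = self.unit.upper()
        if not unit:
            raise ValueError("motif unit must be non-empty")
        bad = set(unit) - _DNA
        if bad:
            raise ValueError(
                f"motif unit {self.unit!r} contains non-ACGT characters: {sorted(bad)}"
            )
        if _smallest_period(unit) != len(unit):
            raise ValueError(
                f"motif unit {self.unit!r} is periodic; use its primitive unit "
                f"{unit[:_smallest_period(unit)]!r}"
            )
        object.__setattr__(self, "unit", unit)
        if not self.label:
            object.__setattr__(self, "label", unit)

    def rotations(self) -> frozenset[str]:
        u = self.unit
        return frozenset(u[i:] + u[:i] for i in range(len(u)))

    def canonical_rotation(self) -> str:
        """Lexicographically smallest rotation; shared by frame-shift-equivalent motifs."""
        return min(self.rotations())


@dataclass(frozen=True)
class RepeatLocus:
    """One maximal run of ``n_units`` exact copies of ``unit``."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    unit: RepeatMotif
    n_units: int
    seq_check: str

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.end - self.start != self.n_units * len(self.unit.unit):
            raise ValueError(
                f"span {self.end - self.start} != {self.n_units} x "
                f"{len(self.unit.unit)} for unit {self.unit.unit}"
            )

    @property
    def start1(self) -> int:
        """1-based inclusive start."""
        return self.start + 1

    @property
    def end1(self) -> int:
        """1-based inclusive end."""
        return self.end


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    min_units
        Minimum number of contiguous full copies for a run to be
        reported (default 4).
    case_sensitive
        When False (default) soft-masked lowercase sequence is scanned
        like uppercase; when True lowercase bases never match and so
        break runs.
    break_on_ambiguous
        When True (default) an N breaks a run and the flanks are
        evaluated independently; when False an N is treated as a
        wildcard matching any motif base.
    dedup_frame_shifts
        Suppress loci wholly contained in a longer locus of a
        rotation-equivalent motif (default False: each motif is an
        independent screen).
    """

    motifs: tuple[RepeatMotif, ...]
    min_units: int = 4
    case_sensitive: bool = False
    break_on_ambiguous: bool = True
    dedup_frame_shifts: bool = False

    def __post_init__(self) -> None:
        motifs = tuple(
            m if isinstance(m, RepeatMotif) else RepeatMotif(str(m)) for m in self.motifs
        )
        if not motifs:
            raise ValueError("motif set must be non-empty")
        units = [m.unit for m in motifs]
        if len(set(units)) != len(units):
            raise ValueError(f"duplicate motif units: {units}")
        if self.min_units < 2:
            raise ValueError("min_units must be >= 2")
        object.__setattr__(self, "motifs", motifs)

    @classmethod
    def default(cls, **kwargs) -> "ScanConfig":
        return cls(motifs=DEFAULT_UNITS, **kwargs)


def _locus_sort_key(locus: RepeatLocus) -> tuple:
    return (locus.chrom, locus.start, locus.unit.unit)


def _validate_sequence(seq: str, chrom: str) -> None:
    m = _INVALID.search(seq)
    if m:
        raise ValueError(
            f"non-DNA character {m.group()!r} at position {m.start()} of {chrom}"
        )


def _motif_pattern(unit: str, config: ScanConfig) -> re.Pattern:
    if config.break_on_ambiguous:
        body = unit
    else:
        body = "".join(f"[{c}N]" for c in unit)
    return re.compile(f"(?:{body}){{{config.min_units},}}")


def scan_sequence(
    seq: str, chrom: str, config: ScanConfig | None = None
) -> list[RepeatLocus]:
    """Find every maximal exact repeat run of each configured motif.

    Greedy leftmost regex matching per motif enumerates exactly the
    maximal runs (motifs are primitive, so same-motif runs cannot
    overlap). Runs of different motifs may overlap. Output is sorted by
    (chrom, start, unit).
    """
    config = config or ScanConfig.default()
    _validate_sequence(seq, chrom)
    hay = seq if config.case_sensitive else seq.upper()
    loci: list[RepeatLocus] = []
    for motif in config.motifs:
        k = len(motif.unit)
        for match in _motif_pattern(motif.unit, config).finditer(hay):
            n = (match.end() - match.start()) // k
            loci.append(
                RepeatLocus(chrom, match.start(), match.start() + n * k, motif, n,
                            hay[match.start():match.start() + n * k])
            )
    if config.dedup_frame_shifts:
        loci = dedup_frame_shifts(loci)
    loci.sort(key=_locus_sort_key)
    return loci


def dedup_frame_shifts(loci: Iterable[RepeatLocus]) -> list[RepeatLocus]:
    """Drop loci wholly contained in a strictly longer rotation-equivalent locus."""
    by_class: dict[tuple, list[RepeatLocus]] = defaultdict(list)
    for locus in loci:
        by_class[(locus.chrom, locus.unit.canonical_rotation())].append(locus)
    keep: list[RepeatLocus] = []
    for group in by_class.values():
        for locus in group:
            contained = any(
                other is not locus
                and other.start <= locus.start
                and locus.end <= other.end
                and (other.end - other.start) > (locus.end - locus.start)
                for other in group
            )
            if not contained:
                keep.append(locus)
    keep.sort(key=_locus_sort_key)
    return keep


def scan_fasta(
    path: str | Path, config: ScanConfig | None = None
) -> Iterator[RepeatLocus]:
    """Stream maximal repeat runs from a (possibly gzipped) FASTA file.

    Records are scanned one at a time in file order; memory use is one
    record's sequence. Duplicate record names are rejected. A progress
    line is logged per record and a total at the end.
    """
    config = config or ScanConfig.default()
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    seen: set[str] = set()
    total = 0
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise ValueError(f"duplicate FASTA record name: {rec.id}")
            seen.add(rec.id)
            found = scan_sequence(str(rec.seq), rec.id, config)
            log.info("scanned %s (%d bp): %d loci", rec.id, len(rec.seq), len(found))
            total += len(found)
            yield from found
    log.info("scan complete: %d loci total", total)


def brute_force_oracle(
    seq: str, chrom: str = "seq", config: ScanConfig | None = None
) -> list[RepeatLocus]:
    """Exhaustive reference enumeration of maximal runs (test oracle only).

    Tests every (start, motif) pair directly against the maximal-run
    definition, independently of the regex path in
    :func:`scan_sequence`. Guarded to short sequences.
    """
    config = config or ScanConfig.default()
    if len(seq) > ORACLE_MAX_LEN:
        raise ValueError(f"oracle guard: sequence longer than {ORACLE_MAX_LEN} bp")
    _validate_sequence(seq, chrom)
    hay = seq if config.case_sensitive else seq.upper()

    def matches(pos: int, unit: str) -> bool:
        if pos < 0 or pos + len(unit) > len(hay):
            return False
        for i, want in enumerate(unit):
            have = hay[pos + i]
            if have == want:
                continue
            if have == "N" and not config.break_on_ambiguous:
                continue
            return False
        return True

    loci: list[RepeatLocus] = []
    for motif in config.motifs:
        k = len(motif.unit)
        for start in range(len(hay)):
            if not matches(start, motif.unit):
                continue
            if matches(start - k, motif.unit):  # not left-maximal
                continue
            n, pos = 0, start
            while matches(pos, motif.unit):
                n += 1
                pos += k
            if n >= config.min_units:
                loci.append(
                    RepeatLocus(chrom, start, start + n * k, motif, n,
                                hay[start:start + n * k])
                )
    if config.dedup_frame_shifts:
        loci = dedup_frame_shifts(loci)
    loci.sort(key=_locus_sort_key)
    return loci


LOCI_TSV_HEADER = ("chrom", "start0", "end0", "start1", "end1", "unit", "n_units")


def write_loci_tsv(loci: Iterable[RepeatLocus], path: str | Path) -> int:
    """Write loci as TSV with both 0-based half-open and 1-based inclusive columns."""
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(LOCI_TSV_HEADER) + "\n")
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t{locus.start1}\t"
                f"{locus.end1}\t{locus.unit.unit}\t{locus.n_units}\n"
            )
            n += 1
    return n


def write_loci_bed(loci: Iterable[RepeatLocus], path: str | Path) -> int:
    """Write loci as BED6 (name=unit:n_units, score=n_units, strand '+')."""
    n = 0
    with open(path, "w") as fh:
        for locus in loci:
            fh.write(
                f"{locus.chrom}\t{locus.start}\t{locus.end}\t"
                f"{locus.unit.unit}:{locus.n_units}\t{locus.n_units}\t+\n"
            )
            n += 1
    return n


def read_loci_tsv(path: str | Path) -> list[RepeatLocus]:
    """Read a loci TSV written by :func:`write_loci_tsv`.

    ``seq_check`` is reconstructed as ``unit * n_units`` since the
    sequence itself is not stored.
    """
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for name in ("chrom", "start0", "end0", "unit", "n_units"):
            if name not in idx:
                raise ValueError(f"loci TSV missing column {name!r} in {path}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            motif = RepeatMotif(f[idx["unit"]])
            n = int(f[idx["n_units"]])
            loci.append(
                RepeatLocus(f[idx["chrom"]], int(f[idx["start0"]]), int(f[idx["end0"]]),
                            motif, n, motif.unit * n)
            )
    return loci
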