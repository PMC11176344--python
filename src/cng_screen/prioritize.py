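"""Length grouping, region-by-length count matrix, and candidate selection.

Annotated loci are binned into three reference-length groups (4-6, 7-9,
and >=10 units), tallied into a (group, unit) x region count matrix,
and filtered by the candidate rule: at least ``min_units`` contiguous
units and an exonic location (CDS or UTR).
"""

from __future__ import annotations

from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotate import AnnotatedLocus, RegionLabel
from .scanner import DEFAULT_UNITS


class LengthGroup(str, Enum):
    GROUP1 = "Group 1"
    GROUP2 = "Group 2"
    GROUP3 = "Group 3"


def assign_group(n_units: int) -> LengthGroup:
    """4-6 units -> Group 1, 7-9 -> Group 2, >=10 -> Group 3."""
    if n_units < 4:
        raise ValueError(f"n_units {n_units} is below the scan minimum of 4")
    if n_units <= 6:
        return LengthGroup.GROUP1
    if n_units <= 9:
        return LengthGroup.GROUP2
    return LengthGroup.GROUP3


#: Region column order of the published count-matrix layout.
REGION_COLUMNS: tuple[RegionLabel, ...] = (
    RegionLabel.CODING,
    RegionLabel.SPLICING,
    RegionLabel.EXONIC_SPLICING,
    RegionLabel.UTR3,
    RegionLabel.UTR5,
    RegionLabel.UTR5_UTR3,
    RegionLabel.INTERGENIC,
    RegionLabel.INTRONIC,
    RegionLabel.NCRNA_EXONIC,
    RegionLabel.NCRNA_INTRONIC,
    RegionLabel.UPSTREAM,
    RegionLabel.DOWNSTREAM,
    RegionLabel.UP_DOWN,
)

TOTAL_COLUMN = "Total loci"


def summarize_matrix(
    annotated: Iterable[AnnotatedLocus],
    units: Sequence[str] = DEFAULT_UNITS,
) -> pd.DataFrame:
    """Count loci per (length group, repeat unit, region label).

    Returns a DataFrame indexed by (group, unit) — all combinations
    present even when zero — with the 13 region columns in the published
    order plus a recomputed row-total column. The grand total of the
    region cells equals the number of input loci.
    """
    units = list(units)
    index = pd.MultiIndex.from_product(
        [[g.value for g in LengthGroup], units], names=["Repeat Category", "Repeat Unit"]
    )
    df = pd.DataFrame(
        0, index=index, columns=[label.value for label in REGION_COLUMNS], dtype=int
    )
    for a in annotated:
        unit = a.locus.unit.unit
        if unit not in units:
            raise ValueError(f"locus unit {unit} not among matrix units {units}")
        group = assign_group(a.locus.n_units)
        df.loc[(group.value, unit), a.label.value] += 1
    df[TOTAL_COLUMN] = df.sum(axis=1)
    return df


def matrix_grand_total(matrix: pd.DataFrame) -> int:
    """Number of loci tallied in the matrix (sum of the row totals)."""
    return int(matrix[TOTAL_COLUMN].sum())


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write the count matrix; the total column is always recomputed from cells."""
    out = matrix.drop(columns=[TOTAL_COLUMN], errors="ignore").copy()
    out[TOTAL_COLUMN] = out.sum(axis=1)
    out.to_csv(path, sep="\t")


#: Exonic region set used for candidate selection; includes the combined
#: labels (they are exonic too). Use PURE_CANDIDATE_REGIONS to restrict.
DEFAULT_CANDIDATE_REGIONS = frozenset(
    {
        RegionLabel.CODING,
        RegionLabel.UTR5,
        RegionLabel.UTR3,
        RegionLabel.EXONIC_SPLICING,
        RegionLabel.UTR5_UTR3,
    }
)

PURE_CANDIDATE_REGIONS = frozenset(
    {RegionLabel.CODING, RegionLabel.UTR5, RegionLabel.UTR3}
)


def select_candidates(
    annotated: Iterable[AnnotatedLocus],
    min_units: int = 10,
    regions: frozenset[RegionLabel] = DEFAULT_CANDIDATE_REGIONS,
) -> list[AnnotatedLocus]:
    """Loci with ``n_units >= min_units`` located in CDS or UTR, input order kept."""
    regions = frozenset(regions)
    if not regions:
        raise ValueError("candidate region set must be non-empty")
    return [
        a for a in annotated if a.locus.n_units >= min_units and a.label in regions
    ]


CANDIDATES_TSV_HEADER = (
    "gene", "transcript", "chrom", "start1", "end1", "unit", "label", "n_units",
)


def write_candidates_tsv(selected: Iterable[AnnotatedLocus], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATES_TSV_HEADER) + "\n")
        for a in selected:
            locus = a.locus
            fh.write(
                f"{a.gene}\t{a.transcript}\t{locus.chrom}\t{locus.start1}\t"
                f"{locus.end1}\t{locus.unit.unit}\t{a.label.value}\t{locus.n_units}\n"
            )
            n += 1
    return n
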