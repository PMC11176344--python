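"""Packaged reference tables from the published hg19 CNG repeat screen.

Three small TSVs ship with the package, transcribed from the printed
results of the genome-wide screen this package re-implements:

* per-(length group, repeat unit) locus totals of the genome-wide scan,
* the 52 exonic candidate loci (>=10 reference units, CDS or UTR) with
  their control-cohort allele ranges and published stability calls,
* the per-cohort summary statistics of the 19 polymorphic loci,
* modal repeat lengths and ranges across 1000 Genomes superpopulations.

They serve as desk-scale inputs for consistency checks — the full-scale
scan needs the hg19 assembly and a matching transcript snapshot, neither
of which is bundled.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .genotype import stability_from_range, DEFAULT_SPAN_THRESHOLD

#: Loci whose published stability call disagrees with the span rule:
#: RAI1 (control range 11-17, span 6) was called unstable despite falling
#: one unit under the span >= 7 threshold.
UNSTABLE_CALL_OVERRIDES: tuple[str, ...] = ("RAI1",)


def _read(name: str) -> pd.DataFrame:
    with resources.files("cng_screen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_group_totals() -> pd.DataFrame:
    """Per-(group, unit) locus totals of the published genome-wide scan."""
    return _read("published_group_totals.tsv")


def load_candidate_loci() -> pd.DataFrame:
    """The 52 published candidate loci with control ranges and stability calls."""
    return _read("published_candidates.tsv")


def load_polymorphic_summaries() -> pd.DataFrame:
    """Per-cohort summary statistics of the 19 polymorphic loci."""
    return _read("published_polymorphic_loci.tsv")


def load_population_mode_ranges() -> pd.DataFrame:
    """Modal repeat length (range) per 1000 Genomes superpopulation and cohort."""
    return _read("published_population_ranges.tsv")


def stability_calls_from_ranges(
    candidates: pd.DataFrame | None = None,
    threshold: int = DEFAULT_SPAN_THRESHOLD,
    overrides: tuple[str, ...] = UNSTABLE_CALL_OVERRIDES,
) -> pd.Series:
    """Recompute stability classes from the candidate control ranges.

    Applies the span rule (max - min >= threshold -> polymorphic) to
    each candidate locus, forcing loci named in ``overrides``
    polymorphic. Returns a Series of 'stable'/'polymorphic' indexed by
    gene.
    """
    if candidates is None:
        candidates = load_candidate_loci()
    calls = {}
    for _, row in candidates.iterrows():
        if row["gene"] in overrides:
            calls[row["gene"]] = "polymorphic"
        else:
            calls[row["gene"]] = stability_from_range(
                int(row["control_min"]), int(row["control_max"]), threshold
            )
    return pd.Series(calls, name="stability")
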