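"""Cohort repeat-length statistics for microsatellite genotypes.

Converts capillary fragment sizes to repeat-unit counts, summarizes the
diploid allele distribution at each locus (range, mode, mean, sample
SD, median, allele counts, heterozygosity), classifies loci as stable
or polymorphic by their length-variability span, and compares cohorts
with Wilcoxon rank-sum / signed-rank tests (exact null distribution for
small tie-free samples, midrank normal approximation with continuity
correction otherwise).

The heterozygosity index (HI) is *observed* heterozygosity: the
fraction of genotyped individuals whose two alleles differ. Expected
heterozygosity (1 - sum of squared allele frequencies) is computed
alongside and reported separately.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

STABLE = "stable"
POLYMORPHIC = "polymorphic"

#: Default span threshold (repeat units): span >= 7 -> polymorphic.
DEFAULT_SPAN_THRESHOLD = 7

#: Largest smaller-sample size for which the exact null distribution is used.
EXACT_LIMIT = 25


@dataclass(frozen=True)
class AlleleCall:
    """One diploid genotype in repeat units; alleles are sorted a1 <= a2."""

    sample: str
    locus: str
    a1: int
    a2: int

    def __post_init__(self) -> None:
        a1, a2 = sorted((int(self.a1), int(self.a2)))
        if a1 < 1:
            raise ValueError(f"allele repeat counts must be >= 1, got {a1}")
        object.__setattr__(self, "a1", a1)
        object.__setattr__(self, "a2", a2)

    @property
    def heterozygous(self) -> bool:
        return self.a1 != self.a2


@dataclass
class CohortTable:
    """All allele calls for one cohort; one call per (sample, locus)."""

    cohort: str
    calls: tuple[AlleleCall, ...]

    def __post_init__(self) -> None:
        self.calls = tuple(self.calls)
        seen = Counter((c.sample, c.locus) for c in self.calls)
        dups = [k for k, v in seen.items() if v > 1]
        if dups:
            raise ValueError(f"duplicate (sample, locus) calls: {dups[:3]}")

    def loci(self) -> list[str]:
        return sorted({c.locus for c in self.calls})

    def calls_at(self, locus: str) -> list[AlleleCall]:
        return [c for c in self.calls if c.locus == locus]

    def alleles_at(self, locus: str) -> np.ndarray:
        """The allele multiset (two per genotyped sample) at one locus."""
        return np.array(
            [a for c in self.calls if c.locus == locus for a in (c.a1, c.a2)], dtype=int
        )


@dataclass(frozen=True)
class LocusSummary:
    """Per-locus allele-distribution statistics (one cohort)."""

    locus: str
    n_chromosomes: int
    n_alleles: int
    min_units: int
    max_units: int
    mode: int
    mean: float
    sd: float
    median: float
    hi: float
    expected_het: float
    stability: str | None = None

    @property
    def span(self) -> int:
        """Length variability: max - min, in repeat units."""
        return self.max_units - self.min_units


def fragment_to_units(fragment_bp: float, flank_bp: int, unit_len: int = 3) -> int:
    """Convert a sized PCR fragment to a repeat-unit count.

    units = round((fragment_bp - flank_bp) / unit_len). A residual of
    more than 1 bp from an exact multiple is logged as a warning
    (off-grid peaks usually mean a mis-specified flank length).
    """
    if unit_len < 1:
        raise ValueError("unit_len must be >= 1")
    if fragment_bp <= flank_bp:
        raise ValueError(
            f"fragment ({fragment_bp} bp) must exceed the flank length ({flank_bp} bp)"
        )
    units = round((fragment_bp - flank_bp) / unit_len)
    residual = abs(fragment_bp - flank_bp - units * unit_len)
    if residual > 1:
        log.warning(
            "fragment %.1f bp is %.1f bp off the repeat grid (flank %d, unit %d)",
            fragment_bp, residual, flank_bp, unit_len,
        )
    return int(units)


def locus_summary(calls: Sequence[AlleleCall], locus: str | None = None) -> LocusSummary:
    """Summary statistics over the allele multiset (two alleles per sample).

    Mode ties break toward the smaller allele; SD is the sample standard
    deviation (n-1 denominator, 0 for a single distinct chromosome
    pair); the median of an even-sized multiset is the mean of the
    central pair. HI is the fraction of heterozygous samples; expected
    heterozygosity is 1 - sum of squared sample allele frequencies.
    """
    if locus is not None:
        calls = [c for c in calls if c.locus == locus]
    else:
        loci = {c.locus for c in calls}
        if len(loci) > 1:
            raise ValueError(f"calls span multiple loci: {sorted(loci)}")
        locus = next(iter(loci)) if loci else None
    if not calls:
        raise ValueError("no calls at locus")
    alleles = np.array([a for c in calls for a in (c.a1, c.a2)], dtype=int)
    counts = Counter(alleles.tolist())
    # max count, ties toward the smaller length
    mode = min(a for a, n in counts.items() if n == max(counts.values()))
    # sorted-allele order keeps float sums identical under input permutation
    freqs = np.array([n for _, n in sorted(counts.items())]) / alleles.size
    return LocusSummary(
        locus=locus,
        n_chromosomes=int(alleles.size),
        n_alleles=len(counts),
        min_units=int(alleles.min()),
        max_units=int(alleles.max()),
        mode=int(mode),
        mean=float(alleles.mean()),
        sd=float(alleles.std(ddof=1)) if alleles.size > 1 else 0.0,
        median=float(np.median(alleles)),
        hi=float(np.mean([c.heterozygous for c in calls])),
        expected_het=float(1.0 - np.sum(freqs**2)),
    )


def stability_from_range(
    min_units: int, max_units: int, threshold: int = DEFAULT_SPAN_THRESHOLD
) -> str:
    """span = max - min; span >= threshold -> polymorphic, else stable."""
    if max_units < min_units:
        raise ValueError("max_units < min_units")
    return POLYMORPHIC if (max_units - min_units) >= threshold else STABLE


def classify_stability(
    summary: LocusSummary,
    threshold: int = DEFAULT_SPAN_THRESHOLD,
    overrides: Iterable[str] = (),
) -> str:
    """Stability class of a locus; ``overrides`` forces named loci polymorphic.

    The override list exists because a published call set may flag a
    locus whose span falls just under the rule's threshold.
    """
    if summary.locus in set(overrides):
        return POLYMORPHIC
    return stability_from_range(summary.min_units, summary.max_units, threshold)


def summarize_cohort(
    cohort: CohortTable,
    threshold: int = DEFAULT_SPAN_THRESHOLD,
    overrides: Iterable[str] = (),
) -> list[LocusSummary]:
    """Per-locus summaries with stability classes, sorted by locus id."""
    out = []
    for locus in cohort.loci():
        s = locus_summary(cohort.calls_at(locus))
        out.append(replace(s, stability=classify_stability(s, threshold, overrides)))
    return out


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    method: str
    n_a: int
    n_b: int


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> ComparisonResult:
    """Wilcoxon rank-sum (Mann-Whitney U) with midranks for ties.

    Exact null distribution when neither sample exceeds
    :data:`EXACT_LIMIT` and there are no ties; otherwise the normal
    approximation with tie correction and continuity correction. Both
    samples identical in value (zero rank variance) gives p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each side needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.unique(pooled).size == 1:
        return ComparisonResult(x.size * y.size / 2.0, 1.0, "degenerate", x.size, y.size)
    ties = np.unique(pooled).size < pooled.size
    if not ties and min(x.size, y.size) <= EXACT_LIMIT:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(
            x, y, alternative=alternative, method="asymptotic", use_continuity=True
        )
        method = "normal-approx"
    return ComparisonResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), method, x.size, y.size
    )


def signed_rank_test(
    x: Sequence[float],
    y: Sequence[float] | None = None,
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Wilcoxon signed-rank on paired values (or precomputed differences).

    Zero differences are dropped; exact null when at most
    :data:`EXACT_LIMIT` nonzero differences and no tied magnitudes,
    normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if d.size < 2:
        raise ValueError("need at least 2 pairs")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        return ComparisonResult(0.0, 1.0, "degenerate", d.size, d.size)
    tied_mag = np.unique(np.abs(nonzero)).size < nonzero.size
    if not tied_mag and nonzero.size <= EXACT_LIMIT:
        res = stats.wilcoxon(d, alternative=alternative, method="exact",
                             zero_method="wilcox")
        method = "exact"
    else:
        res = stats.wilcoxon(d, alternative=alternative, method="approx",
                             correction=True, zero_method="wilcox")
        method = "normal-approx"
    return ComparisonResult(
        float(res.statistic), float(min(res.pvalue, 1.0)), method, d.size, d.size
    )


def compare_cohorts(
    a: CohortTable,
    b: CohortTable,
    locus: str | None = None,
    mode: str = "rank_sum",
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Nonparametric comparison of two cohorts.

    ``rank_sum`` compares the allele multisets of the two cohorts at one
    locus. ``signed_rank`` pairs the per-locus modal allele lengths of
    the two cohorts across their shared loci (the pairing unit is the
    locus, not the sample). The method actually used is logged.
    """
    if mode == "rank_sum":
        if locus is None:
            raise ValueError("rank_sum mode requires a locus")
        result = rank_sum_test(a.alleles_at(locus), b.alleles_at(locus), alternative)
    elif mode == "signed_rank":
        shared = sorted(set(a.loci()) & set(b.loci()))
        if len(shared) < 2:
            raise ValueError("signed_rank mode needs >= 2 shared loci")
        modes_a = [locus_summary(a.calls_at(l)).mode for l in shared]
        modes_b = [locus_summary(b.calls_at(l)).mode for l in shared]
        result = signed_rank_test(np.array(modes_a), np.array(modes_b), alternative)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    log.info(
        "compare %s vs %s (%s%s): %s p=%.4g",
        a.cohort, b.cohort, mode, f" @ {locus}" if locus else "",
        result.method, result.p_value,
    )
    return result


# ---------------------------------------------------------------------------
# I/O

def read_calls_tsv(
    path: str | Path, locus_config: str | Path | None = None
) -> dict[str, CohortTable]:
    """Read genotype calls, one cohort table per cohort name.

    Accepts either unit columns (``sample cohort locus a1_units
    a2_units``) or raw fragment sizes (``sample cohort locus frag1_bp
    frag2_bp``); the latter requires a per-locus config TSV
    (``locus flank_bp unit_len``) for conversion.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "cohort", "locus"}
    if not required <= set(df.columns):
        raise ValueError(f"calls TSV must have columns {sorted(required)}")
    if {"a1_units", "a2_units"} <= set(df.columns):
        a1, a2 = df["a1_units"], df["a2_units"]
    elif {"frag1_bp", "frag2_bp"} <= set(df.columns):
        if locus_config is None:
            raise ValueError("fragment-size calls require a locus config TSV")
        cfg = pd.read_csv(locus_config, sep="\t").set_index("locus")
        a1, a2 = [], []
        for _, row in df.iterrows():
            c = cfg.loc[row["locus"]]
            a1.append(fragment_to_units(row["frag1_bp"], int(c["flank_bp"]),
                                        int(c["unit_len"])))
            a2.append(fragment_to_units(row["frag2_bp"], int(c["flank_bp"]),
                                        int(c["unit_len"])))
    else:
        raise ValueError("calls TSV needs a1_units/a2_units or frag1_bp/frag2_bp")
    df = df.assign(_a1=a1, _a2=a2)
    out = {}
    for cohort, sub in df.groupby("cohort", sort=True):
        calls = tuple(
            AlleleCall(str(r["sample"]), str(r["locus"]), int(r["_a1"]), int(r["_a2"]))
            for _, r in sub.iterrows()
        )
        out[str(cohort)] = CohortTable(str(cohort), calls)
    return out


SUMMARY_TSV_HEADER = (
    "locus", "n_chromosomes", "n_alleles", "min_units", "max_units", "mode",
    "mean", "sd", "median", "hi", "expected_het", "stability",
)


def write_summary_tsv(summaries: Iterable[LocusSummary], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("\t".join(SUMMARY_TSV_HEADER) + "\n")
        for s in summaries:
            fh.write(
                f"{s.locus}\t{s.n_chromosomes}\t{s.n_alleles}\t{s.min_units}\t"
                f"{s.max_units}\t{s.mode}\t{s.mean:.2f}\t{s.sd:.2f}\t{s.median:.1f}\t"
                f"{s.hi:.2f}\t{s.expected_het:.2f}\t{s.stability or ''}\n"
            )
            n += 1
    return n


def read_summary_tsv(path: str | Path) -> list[LocusSummary]:
    """Read a summary TSV written by :func:`write_summary_tsv`."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        stability = r.get("stability")
        if pd.isna(stability) or stability == "":
            stability = None
        out.append(
            LocusSummary(
                locus=str(r["locus"]),
                n_chromosomes=int(r["n_chromosomes"]),
                n_alleles=int(r["n_alleles"]),
                min_units=int(r["min_units"]),
                max_units=int(r["max_units"]),
                mode=int(r["mode"]),
                mean=float(r["mean"]),
                sd=float(r["sd"]),
                median=float(r["median"]),
                hi=float(r["hi"]),
                expected_het=float(r["expected_het"]),
                stability=stability,
            )
        )
    return out


def write_stability_tsv(summaries: Iterable[LocusSummary], path: str | Path) -> int:
    """Range + class per locus (published-range table style)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("locus\trange\tspan\tstability\n")
        for s in summaries:
            fh.write(f"{s.locus}\t{s.min_units}-{s.max_units}\t{s.span}\t"
                     f"{s.stability or ''}\n")
            n += 1
    return n


def write_compare_tsv(
    results: Mapping[str, ComparisonResult], path: str | Path
) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("comparison\tstatistic\tp_value\tmethod\tn_a\tn_b\n")
        for name, r in results.items():
            fh.write(f"{name}\t{r.statistic:.6g}\t{r.p_value:.6g}\t{r.method}\t"
                     f"{r.n_a}\t{r.n_b}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# External STR catalogs (per-population allele-count tables)

CATALOG_COLUMNS = ("population", "locus", "allele_units", "count")


def load_external_catalog(path: str | Path) -> pd.DataFrame:
    """Load a per-population STR allele-count TSV.

    Columns: population, locus, allele_units, count. Malformed rows are
    rejected with their line number; an empty file yields an empty
    catalog with a warning.
    """
    rows = []
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            log.warning("external catalog %s is empty", path)
            return pd.DataFrame(columns=CATALOG_COLUMNS)
        cols = header.rstrip("\n").split("\t")
        if tuple(cols) != CATALOG_COLUMNS:
            raise ValueError(
                f"line 1: expected columns {CATALOG_COLUMNS}, got {tuple(cols)}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 4:
                raise ValueError(f"line {lineno}: expected 4 fields, got {len(f)}")
            try:
                rows.append((f[0], f[1], int(f[2]), int(f[3])))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from None
            if rows[-1][2] < 1 or rows[-1][3] < 0:
                raise ValueError(f"line {lineno}: allele_units must be >= 1 and "
                                 "count >= 0")
    if not rows:
        log.warning("external catalog %s has a header but no rows", path)
    return pd.DataFrame(rows, columns=CATALOG_COLUMNS)


def catalog_alleles(catalog: pd.DataFrame, population: str, locus: str) -> np.ndarray:
    """Expand one (population, locus) entry to its allele multiset."""
    sub = catalog[(catalog["population"] == population) & (catalog["locus"] == locus)]
    return np.repeat(sub["allele_units"].to_numpy(), sub["count"].to_numpy())


def catalog_report(catalog: pd.DataFrame) -> pd.DataFrame:
    """Per (population, locus): mode and range, formatted ``mode (min-max)``.

    Mode ties break toward the smaller allele, matching the cohort
    summaries.
    """
    records = []
    for (pop, locus), sub in catalog.groupby(["population", "locus"], sort=True):
        alleles = np.repeat(sub["allele_units"].to_numpy(), sub["count"].to_numpy())
        if alleles.size == 0:
            continue
        counts = Counter(alleles.tolist())
        mode = min(a for a, n in counts.items() if n == max(counts.values()))
        records.append(
            {
                "population": pop,
                "locus": locus,
                "mode": int(mode),
                "min_units": int(alleles.min()),
                "max_units": int(alleles.max()),
                "display": f"{int(mode)} ({int(alleles.min())}-{int(alleles.max())})",
            }
        )
    return pd.DataFrame(
        records,
        columns=["population", "locus", "mode", "min_units", "max_units", "display"],
    )


def expected_heterozygosity(freqs: Sequence[float]) -> float:
    """1 - sum p_i^2 for an allele-frequency spectrum."""
    freqs = np.asarray(freqs, dtype=float)
    if not math.isclose(float(freqs.sum()), 1.0, abs_tol=1e-9):
        raise ValueError("allele frequencies must sum to 1")
    return float(1.0 - np.sum(freqs**2))
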