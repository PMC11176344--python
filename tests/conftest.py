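import numpy as np
import pytest

from cng_screen import (
    GeneModel,
    PlantSpec,
    RegionLabel,
    make_gene_model,
    make_genome,
)

L = RegionLabel

#: Planted loci covering every satisfiable region label, spaced >= 5 kb so the
#: synthetic gene constructs cannot interfere with each other.
PLANT_SPECS = (
    PlantSpec("chr1", 6000, "CAG", 12, L.CODING),
    PlantSpec("chr1", 12000, "CTG", 11, L.UTR5),
    PlantSpec("chr1", 18000, "CGG", 10, L.UTR3),
    PlantSpec("chr1", 24000, "CAG", 8, L.INTRONIC),
    PlantSpec("chr1", 30000, "CTG", 5, L.UPSTREAM),
    PlantSpec("chr1", 36000, "CAG", 6, None),  # intergenic
    PlantSpec("chr2", 6000, "CAG", 10, L.NCRNA_EXONIC),
    PlantSpec("chr2", 12000, "CAG", 10, L.UP_DOWN),
    PlantSpec("chr2", 18000, "CTG", 10, L.EXONIC_SPLICING, strand="-"),
    PlantSpec("chr2", 24000, "CTG", 7, L.SPLICING),
    PlantSpec("chr2", 30000, "CAG", 4, L.DOWNSTREAM),
    PlantSpec("chr2", 36000, "CTG", 6, L.NCRNA_INTRONIC),
    PlantSpec("chr2", 42000, "CAG", 11, L.UTR5, strand="-"),
)

CHROM_LENGTHS = {"chr1": 42000, "chr2": 48000}


@pytest.fixture(scope="session")
def planted_genome():
    """(records, truth) for the standard planted-locus fixture, seed 7."""
    return make_genome(PLANT_SPECS, CHROM_LENGTHS, seed=7)


@pytest.fixture(scope="session")
def planted_gene_model():
    """(GeneModel, label truth table) matching the planted genome."""
    transcripts, truth = make_gene_model(PLANT_SPECS)
    return GeneModel(tuple(transcripts)), truth


def random_dna(rng: np.random.Generator, length: int, n_frac: float = 0.0) -> str:
    bases = "ACGTN" if n_frac > 0 else "ACGT"
    p = None
    if n_frac > 0:
        p = [(1 - n_frac) / 4] * 4 + [n_frac]
    return "".join(rng.choice(list(bases), size=length, p=p))
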