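import random

import pytest

from deldesign.fixtures import (
    PlantedSite,
    SyntheticGenomeSpec,
    synth_genome,
    write_fixture_files,
)
from deldesign.genome_index import GenomeSequence, index_genome


def random_spacer(rng: random.Random) -> str:
    return "".join(rng.choice("ACGT") for _ in range(20))


def random_genome(rng: random.Random, length: int, name: str = "I") -> GenomeSequence:
    return GenomeSequence({name: "".join(rng.choice("ACGT") for _ in range(length))})


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """CLI-level fixture files (FASTA + GFF3 + TSV), seed 42."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return write_fixture_files(outdir, seed=42)


@pytest.fixture(scope="session")
def planted_genome():
    """2-kb genome with three unique planted sites and one duplicated spacer."""
    rng = random.Random(7)
    spec = SyntheticGenomeSpec(seed=7, chrom_lengths={"I": 2000})
    uniques = [random_spacer(rng) for _ in range(3)]
    for spacer, pos in zip(uniques, (500, 600, 700)):
        spec.plant("I", PlantedSite(spacer, "TGG", "+", position=pos))
    dup = random_spacer(rng)
    spec.plant("I", PlantedSite(dup, "AGG", "+", copies=2))
    genome, truth = synth_genome(spec)
    return genome, truth, uniques, dup


@pytest.fixture(scope="session")
def planted_index(planted_genome):
    genome = planted_genome[0]
    return index_genome(genome)
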