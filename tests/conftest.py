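import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

from ssrmine.synthetic_data import (
    PlantedSSR,
    SyntheticGenomeSpec,
    generate_genome,
)


@pytest.fixture(scope="session")
def small_planted_genome():
    """3 chromosomes x 50 kb with 60 planted SSRs across all regions."""
    from ssrmine.synthetic_data import study_genome_spec

    spec = study_genome_spec(seed=7, n_chromosomes=3, chromosome_length=50_000, n_loci=60)
    return spec, generate_genome(spec)


@pytest.fixture(scope="session")
def tiny_planted_genome():
    """One 20 kb chromosome with a handful of hand-picked planted loci."""
    spec = SyntheticGenomeSpec(
        chromosome_lengths=[20_000],
        planted=[
            PlantedSSR("AC", 8, "intergenic"),
            PlantedSSR("AT", 6, "intron"),
            PlantedSSR("AAG", 7, "exon"),
            PlantedSSR("ATC", 5, "intron"),
            PlantedSSR("AAAT", 5, "intergenic"),
            PlantedSSR("AACCT", 5, "exon"),
            PlantedSSR("AACCGT", 5, "intergenic"),
        ],
        seed=11,
    )
    return spec, generate_genome(spec)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
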