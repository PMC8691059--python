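import numpy as np
import pytest

from svcmr.events import Category
from svcmr.simulate import (
    GeneConfig,
    GenomeConfig,
    PopulationConfig,
    SimulationConfig,
)


def small_config(
    rates: dict | None = None,
    n_contigs: int = 2,
    contig_length: int = 200_000,
    lines_per_genotype: int = 4,
    generations: int = 12,
    n_genes: int = 50,
    seed: int = 0,
) -> SimulationConfig:
    """A compact experiment design for fast unit tests."""
    rates = rates or {cat: 1e-8 for cat in Category}
    pops = [
        PopulationConfig("Finland", 1, dict(rates)),
        PopulationConfig("Germany", 1, dict(rates)),
        PopulationConfig("Israel", 1, dict(rates)),
    ]
    return SimulationConfig(
        populations=pops,
        lines_per_genotype=lines_per_genotype,
        generations=generations,
        genome=GenomeConfig(n_contigs=n_contigs, contig_length=contig_length),
        genes=GeneConfig(count=n_genes, mean_length=1_000),
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
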