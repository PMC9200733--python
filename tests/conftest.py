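import dataclasses

import numpy as np
import pytest

from mitoqc import (
    CircularSequence,
    ErrorModel,
    SimulationConfig,
    inject_errors,
    simulate_mitogenome,
)
from mitoqc.records import GeneAnnotation

BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int, at: float = 0.5) -> str:
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(BASES[rng.choice(4, size=n, p=p)])


@pytest.fixture(scope="session")
def sim_genome():
    """One default synthetic mitogenome shared across tests."""
    return simulate_mitogenome(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def sim_pair(sim_genome):
    """Genome plus an ONT-like corrupted copy and its truth differences."""
    genome, annotations = sim_genome
    corrupted, truth = inject_errors(genome, ErrorModel(seed=12))
    return genome, corrupted, truth


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_order(names_strands, gene_class="PCG", gene_len=90, spacing=100):
    """Annotation list laying out genes in the given signed order."""
    return [
        GeneAnnotation(name, gene_class, i * spacing, i * spacing + gene_len, strand)
        for i, (name, strand) in enumerate(names_strands)
    ]


@pytest.fixture(scope="session")
def full_annotation_set(sim_genome):
    """The 37-gene complement (control region excluded)."""
    _, annotations = sim_genome
    return [a for a in annotations if a.gene_class != "other"]
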