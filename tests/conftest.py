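import numpy as np
import pytest

from ssrmine.io_formats import GenomeSeq
from ssrmine.simulate import SimConfig, simulate_panel

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


@pytest.fixture(scope="session")
def small_panel():
    """A 3-genome, 40-locus synthetic panel shared by the slower tests."""
    cfg = SimConfig(
        seed=11,
        n_genomes=3,
        n_loci=40,
        contig_lengths=[60_000],
        duplication_rate=0.10,
    )
    return cfg, simulate_panel(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_genome(seq: str, genome_id: str = "g", seq_id: str = "c1") -> GenomeSeq:
    return GenomeSeq(genome_id=genome_id, records=[(seq_id, seq)])
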