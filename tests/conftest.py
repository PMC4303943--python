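import numpy as np
import pytest

from introscan import simulate as sim


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_parents():
    """A 20-Mbp single-chromosome parental pair, shared across tests."""
    spec = sim.GenomeSpec(
        chromosomes=(("chr1", 20_000_000),), snp_density=25.0, seed=41
    )
    return sim.simulate_parental_genomes(spec)


@pytest.fixture(scope="session")
def focal_parents():
    """The study-scale 290-Mbp chromosome with default density."""
    spec = sim.GenomeSpec(
        chromosomes=(("chr1", 290_000_000),), snp_density=15.0, seed=7
    )
    return sim.simulate_parental_genomes(spec)


@pytest.fixture
def toy_gene():
    """Plus-strand single-exon toy gene: ATG GCT TGC TAA-free filler."""
    from introscan.io import GeneModel

    return GeneModel(
        gene_id="toy1",
        symbol="Toy1",
        chrom="chrT",
        strand="+",
        cds_intervals=[(101, 112)],
        coding_sequence="ATGGCTTGCCAA",
    )
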