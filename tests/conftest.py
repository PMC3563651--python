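import numpy as np
import pytest

from famarch import GenomeAnnotation, simulate_genome_pair


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Ten genes on two chromosomes with simple geometry."""
    rows = []
    for c, chrom in enumerate(["chr1", "chr2"], start=1):
        for i in range(5):
            start = 1000 * i + 1
            rows.append((f"{chrom}_g{i + 1}", chrom, start, start + 500, "+"))
    return GenomeAnnotation(rows)


@pytest.fixture(scope="session")
def small_pair():
    """A modest simulated genome pair reused by read-only tests."""
    return simulate_genome_pair(
        n_chromosomes=3, genes_per_chromosome=80, family_fraction=0.1,
        wgd_retention_a=0.6, n_tandem_b=10, seed=11,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
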