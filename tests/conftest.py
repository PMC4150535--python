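import numpy as np
import pytest

from snipscan import GenotypeDataset, SnpRecord, default_curve


@pytest.fixture(scope="session")
def mult_curve():
    """The shipped multiplicative partner-score curve."""
    return default_curve("multiplicative")


def make_dataset(genotypes, phenotype=None, positions=None, chrom="1",
                 phenotype_type="binary"):
    """Assemble a GenotypeDataset from a raw dosage matrix."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if positions is None:
        positions = [1000 * (j + 1) for j in range(m)]
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    snps = [
        SnpRecord(chroms[j], f"snp{j + 1}", 0.0, positions[j], "A", "B")
        for j in range(m)
    ]
    if phenotype is None:
        phenotype = np.tile([0.0, 1.0], n)[:n]
    return GenotypeDataset(
        genotypes=genotypes,
        snps=snps,
        phenotype=np.asarray(phenotype, dtype=float),
        phenotype_type=phenotype_type,
        individual_ids=[f"i{k}" for k in range(n)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
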