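import numpy as np
import pytest

from radpop.genotype_io import MISSING, GenotypeMatrix, Locus


def make_loci(n, chrom="chr01", spacing=1000, start=1000):
    """Evenly spaced biallelic loci on one chromosome."""
    return [
        Locus(chrom=chrom, pos=start + i * spacing, ref="A", alt="G", id=f"L{i}")
        for i in range(n)
    ]


def random_matrix(rng, n=10, L=50, missing_rate=0.1):
    """Random dosage matrix with MCAR missingness, for oracle-style tests."""
    dosage = rng.integers(0, 3, size=(n, L)).astype(np.int8)
    if missing_rate:
        dosage[rng.random((n, L)) < missing_rate] = MISSING
    return GenotypeMatrix(
        samples=[f"S{i}" for i in range(n)], loci=make_loci(L), dosage=dosage
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_gm():
    """3 samples x 2 loci with the hand-readable dosage pattern."""
    dosage = np.array([[0, 2], [1, 1], [2, MISSING]], dtype=np.int8)
    return GenotypeMatrix(samples=["a", "b", "c"], loci=make_loci(2), dosage=dosage)
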