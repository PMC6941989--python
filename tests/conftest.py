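import numpy as np
import pytest

from supergene.variants import GenotypeMatrix


def random_genotype_matrix(
    rng,
    n_ind: int = 12,
    n_sites: int = 20,
    missing_rate: float = 0.0,
    phased: bool = False,
    chrom: str = "chr1",
) -> GenotypeMatrix:
    """Random biallelic matrix with controllable missingness/phase."""
    pos = np.sort(rng.choice(np.arange(1, 200_000), size=n_sites, replace=False))
    if phased:
        haps = rng.integers(0, 2, size=(n_ind, 2, n_sites)).astype(np.int8)
        dosage = haps.sum(axis=1).astype(np.int8)
        if missing_rate:
            miss = rng.random((n_ind, n_sites)) < missing_rate
            haps[miss[:, None, :].repeat(2, axis=1)] = -1
            dosage[miss] = -1
        g = GenotypeMatrix(
            ids=[f"i{k}" for k in range(n_ind)],
            chrom=np.array([chrom] * n_sites, dtype=object),
            pos=pos,
            ref=np.array(["A"] * n_sites, dtype=object),
            alt=np.array(["T"] * n_sites, dtype=object),
            dosage=dosage,
            haplotypes=haps,
        )
    else:
        dosage = rng.integers(0, 3, size=(n_ind, n_sites)).astype(np.int8)
        if missing_rate:
            dosage[rng.random((n_ind, n_sites)) < missing_rate] = -1
        g = GenotypeMatrix(
            ids=[f"i{k}" for k in range(n_ind)],
            chrom=np.array([chrom] * n_sites, dtype=object),
            pos=pos,
            ref=np.array(["A"] * n_sites, dtype=object),
            alt=np.array(["T"] * n_sites, dtype=object),
            dosage=dosage,
        )
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
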