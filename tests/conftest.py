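import numpy as np
import pytest

from pathartp.dataset import CASE, CONTROL, GenotypeDataset, SampleMeta, SnpMeta
from pathartp.simulate import exhaustive_permutation_dataset, qc_violation_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def qc_fixture():
    """30-sample dataset with one SNP engineered to fail each QC filter."""
    return qc_violation_dataset()


@pytest.fixture(scope="session")
def exhaustive8():
    """8 samples (4 cases), 3 genes x 2 SNPs: C(8,4)=70 relabelings."""
    return exhaustive_permutation_dataset(seed=42)


def random_dataset(rng, n=30, m=6, maf_low=0.1, maf_high=0.5, missing=0.0):
    """Small random dataset with HWE genotypes, for round-trip style tests."""
    mafs = rng.uniform(maf_low, maf_high, size=m)
    h = rng.random((n, m, 2)) < mafs[None, :, None]
    X = h.sum(axis=2).astype(float)
    if missing:
        X[rng.random((n, m)) < missing] = np.nan
    status = np.array([CASE] * (n // 2) + [CONTROL] * (n - n // 2))
    samples = [SampleMeta(f"id{i}", status[i]) for i in range(n)]
    alleles = [("A", "C"), ("G", "T"), ("C", "G")]
    snps = [
        SnpMeta(f"rs{j}", str(j % 3 + 1), 1000 * (j + 1), *alleles[j % 3])
        for j in range(m)
    ]
    from pathartp.dataset import orient_to_minor

    X, flipped = orient_to_minor(X)
    for j in np.flatnonzero(flipped):
        s = snps[j]
        snps[j] = SnpMeta(s.snp_id, s.chromosome, s.position,
                          s.allele_major, s.allele_minor)
    return GenotypeDataset(X, samples, snps)
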