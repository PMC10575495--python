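import numpy as np
import pytest

from ldhs.genotype_data import GenotypeDataset
from ldhs.objectives import ContingencyTable


def dataset_from_cells(case_counts, control_counts):
    """Build a k=1 dataset whose genotype-value tallies equal the given counts.

    ``case_counts[s]`` / ``control_counts[s]`` are the numbers of case and
    control samples with genotype value s (s = 0, 1, 2). Useful for writing
    contingency tables by hand.
    """
    geno, labels = [], []
    for s, (nca, nco) in enumerate(zip(case_counts, control_counts)):
        geno.extend([s] * (nca + nco))
        labels.extend([1] * nca + [0] * nco)
    return GenotypeDataset(
        snp_ids=["S0"],
        genotypes=np.array(geno, dtype=np.int8).reshape(-1, 1),
        labels=np.array(labels, dtype=np.int8),
    )


def table_from_rows(rows):
    """ContingencyTable from explicit [case, control] rows (padded to 3 cells, k=1)."""
    rows = list(rows)
    assert len(rows) <= 3
    counts = np.zeros((3, 2), dtype=np.int64)
    for i, (nca, nco) in enumerate(rows):
        counts[i] = (nca, nco)
    return ContingencyTable(k=1, counts=counts, locus_marginals=counts.reshape(1, 3, 2))


def random_dataset(rng, n=40, m=8, case_fraction=0.5):
    geno = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    labels = (rng.random(n) < case_fraction).astype(np.int8)
    return GenotypeDataset(
        snp_ids=[f"S{j}" for j in range(m)], genotypes=geno, labels=labels
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
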