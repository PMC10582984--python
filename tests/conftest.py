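import numpy as np
import pandas as pd
import pytest

from bcellprs.matrix import GenotypeMatrix
from bcellprs.scoring import packaged_weight_table


@pytest.fixture(scope="session")
def weight_table():
    return packaged_weight_table()


@pytest.fixture
def rng():
    return np.random.default_rng(20230926)


def make_matrix(dosages, snp_ids=None, alleles=None, is_x=None, sample_ids=None,
                annotated_sex=None):
    """Build a GenotypeMatrix from a plain dosage array (NaN = missing)."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if snp_ids is None:
        snp_ids = [f"snp{j + 1}" for j in range(m)]
    if alleles is None:
        alleles = [("A", "G")] * m
    if is_x is None:
        is_x = [False] * m
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": ["X" if x else "1" for x in is_x],
            "pos": np.arange(1, m + 1),
            "allele_a": [a for a, _ in alleles],
            "allele_b": [b for _, b in alleles],
            "is_x": is_x,
        }
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        variants=variants,
        dosages=d,
        annotated_sex=annotated_sex or {},
    )


@pytest.fixture
def table_matrix(weight_table):
    """All-homozygous-risk and all-zero samples at the packaged loci."""
    m = len(weight_table)
    dosages = np.vstack([np.full(m, 2.0), np.zeros(m), np.ones(m), np.full(m, 2.0)])
    return make_matrix(
        dosages,
        snp_ids=[v.snp_id for v in weight_table],
        alleles=[(v.other_allele, v.risk_allele) for v in weight_table],
    )
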