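import numpy as np
import pytest

from mrkit.calibration import hset_from_arrays
from mrkit.sumstats import SummaryStatsTable, VariantAssociation


def make_variant(
    variant_id="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.3,
    beta=0.1,
    se=0.01,
    pvalue=1e-10,
    n=100_000,
):
    return VariantAssociation(
        variant_id=variant_id, chrom=chrom, pos=pos,
        effect_allele=effect_allele, other_allele=other_allele,
        eaf=eaf, beta=beta, se=se, pvalue=pvalue, n=n,
    )


@pytest.fixture
def small_table():
    """Three-variant continuous-trait table."""
    records = [
        make_variant("rs1", beta=0.10, se=0.010, pvalue=1e-9),
        make_variant("rs2", effect_allele="C", other_allele="T", beta=-0.05,
                     se=0.008, pvalue=4e-8, eaf=0.2, pos=2000),
        make_variant("rs3", effect_allele="T", other_allele="G", beta=0.02,
                     se=0.012, pvalue=6e-8, eaf=0.4, pos=3000),
    ]
    return SummaryStatsTable("trait_a", "continuous", records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_hset():
    """Five instruments exactly on Gamma = 0.3 * gamma (no pleiotropy)."""
    bx = np.array([0.05, 0.08, 0.10, 0.12, 0.15])
    by = 0.3 * bx
    sx = np.full(5, 0.01)
    sy = np.array([0.010, 0.012, 0.009, 0.011, 0.010])
    return hset_from_arrays(bx, sx, by, sy)
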