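import numpy as np
import pytest

import metabomr as mm


@pytest.fixture
def two_snp_set() -> mm.InstrumentSet:
    """Two instruments with unit outcome SEs; IVW theta=1, Q=0.5 by hand."""
    return mm.InstrumentSet.from_arrays(
        beta_exp=[1.0, 1.0], se_exp=[0.01, 0.01],
        beta_out=[0.5, 1.5], se_out=[1.0, 1.0],
    )


@pytest.fixture
def exact_line_set() -> mm.InstrumentSet:
    """Three points on the exact line beta_Y = 0.1 + 0.5*beta_X."""
    return mm.InstrumentSet.from_arrays(
        beta_exp=[1.0, 2.0, 3.0], se_exp=[0.01] * 3,
        beta_out=[0.6, 1.1, 1.6], se_out=[1.0] * 3,
    )


def make_record(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.01,
                pvalue=1e-10, chrom="1", pos=100_000, eaf=0.3, n=10_000):
    return mm.SummaryStatRecord(
        snp_id=snp_id, effect_allele=ea, other_allele=oa, beta=beta, se=se,
        pvalue=pvalue, chrom=chrom, pos=pos, eaf=eaf, n=n,
    )


@pytest.fixture
def random_sets():
    """Small random instrument sets for oracle-equivalence checks."""
    rng = np.random.default_rng(20240901)
    sets = []
    for _ in range(50):
        k = int(rng.integers(2, 12))
        bx = rng.normal(0.05, 0.03, k)
        bx[np.abs(bx) < 1e-3] = 0.05
        sets.append(
            mm.InstrumentSet.from_arrays(
                beta_exp=bx,
                se_exp=rng.uniform(0.003, 0.01, k),
                beta_out=rng.normal(0.0, 0.05, k),
                se_out=rng.uniform(0.005, 0.05, k),
            )
        )
    return sets
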