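import numpy as np
import pytest

from lipidmr.gwas_io import GwasRecord, HarmonizedPair, SummaryTable


def make_pair(snp_id="rs1", bx=0.1, sx=0.01, by=0.05, sy=0.01, eaf=0.3, action="kept"):
    return HarmonizedPair(
        snp_id=snp_id,
        beta_exposure=bx,
        se_exposure=sx,
        beta_outcome=by,
        se_outcome=sy,
        eaf_exposure=eaf,
        action=action,
    )


def make_record(
    snp_id="rs1",
    chrom="1",
    pos=1000,
    ea="A",
    oa="G",
    beta=0.1,
    se=0.01,
    pval=1e-10,
    eaf=0.3,
    n=100000.0,
):
    return GwasRecord(
        snp_id=snp_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        beta=beta,
        se=se,
        pval=pval,
        eaf=eaf,
        n=n,
    )


@pytest.fixture
def ivw_example_pairs():
    """Three instruments with Wald ratios (0.5, 0.4, 0.6), all se_theta 0.1.

    Hand-computed oracle: equal weights 100 give IVW beta 0.5,
    fixed-effect se sqrt(1/300), Cochran Q = 2.0 on 2 df.
    """
    return [
        make_pair("rs1", bx=0.1, by=0.05, sy=0.01),
        make_pair("rs2", bx=0.2, by=0.08, sy=0.02),
        make_pair("rs3", bx=0.5, by=0.30, sy=0.05),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240606)
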