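import numpy as np
import pytest

from tsmr.summary_io import SummaryDataset, SummaryStatRecord


def make_record(
    rsid="rs1",
    chrom="1",
    pos=1000,
    effect_allele="A",
    other_allele="G",
    eaf=0.2,
    beta=0.05,
    se=0.01,
    pvalue=1e-6,
    n=100_000.0,
):
    return SummaryStatRecord(
        rsid=rsid,
        chrom=chrom,
        pos=pos,
        effect_allele=effect_allele,
        other_allele=other_allele,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


def make_dataset(records, trait_name="exposure", trait_type="continuous", **kw):
    return SummaryDataset(
        trait_name=trait_name, trait_type=trait_type, records=list(records), **kw
    )


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture
def dataset_factory():
    return make_dataset


@pytest.fixture
def small_dataset():
    """Three well-separated SNPs on different chromosomes."""
    return make_dataset(
        [
            make_record(rsid="rs1", chrom="1", pos=1_000_000, pvalue=1e-8),
            make_record(rsid="rs2", chrom="2", pos=2_000_000, pvalue=1e-6, beta=0.04),
            make_record(rsid="rs3", chrom="3", pos=3_000_000, pvalue=1e-7, beta=0.06),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
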