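import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from microdna import GeneModel, MicroDNACall, SampleMeta

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_call(chrom="chr1", start=0, end=100, strand="+", support=2, call_id=""):
    return MicroDNACall(
        chrom=chrom, start=start, end=end, strand=strand, support=support, call_id=call_id
    )


@pytest.fixture
def toy_plus_gene():
    """Coding + strand gene with distinct promoter/5'UTR/exon/intron/3'UTR zones.

    Promoter [8000,10000); 5'UTR [10000,12000); coding exon parts
    [12000,12500), [20000,21000), [37500,38000); introns [12500,20000) and
    [21000,37500); 3'UTR [38000,40000).
    """
    return GeneModel(
        gene_name="AASS",
        chrom="chr7",
        strand="+",
        tx_start=10_000,
        tx_end=40_000,
        cds_start=12_000,
        cds_end=38_000,
        exon_starts=(10_000, 20_000, 37_500),
        exon_ends=(12_500, 21_000, 40_000),
    )


@pytest.fixture
def toy_minus_gene():
    """Coding - strand gene: promoter [130000,132000) on the right of the span;
    5'UTR [128000,130000); 3'UTR [100000,102000)."""
    return GeneModel(
        gene_name="KBTBD11",
        chrom="chr8",
        strand="-",
        tx_start=100_000,
        tx_end=130_000,
        cds_start=102_000,
        cds_end=128_000,
        exon_starts=(100_000, 119_000, 127_500),
        exon_ends=(102_500, 121_000, 130_000),
    )


def plasma_meta(patient, stage, mapped_reads=3_500_000):
    tag = {"diagnosis": "dx", "relapse": "rel", "remission": "rem"}[stage]
    return SampleMeta(
        sample_id=f"{patient}_{tag}_plasma",
        patient_id=patient,
        tissue="plasma",
        stage=stage,
        mapped_reads=mapped_reads,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
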