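import textwrap

import pytest

from cehkit.core import GenomicRegion, ReferenceTrack


FIVE_RECORD_VCF = textwrap.dedent(
    """\
    ##fileformat=VCFv4.2
    ##contig=<ID=chr6>
    ##FILTER=<ID=LowQual,Description="low">
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
    chr6\t101\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0
    chr6\t205\t.\tC\tT\t.\tLowQual\t.\tGT\t1/1\t0/1
    chr6\t310\t.\tG\tA\t.\tPASS\t.\tGT\t./.\t1|0
    chr6\t420\t.\tT\tTAG\t.\tPASS\t.\tGT\t0/1\t0/0
    chr6\t530\t.\tGTT\tG\t.\tPASS\t.\tGT\t1/1\t0/1
    """
)


@pytest.fixture
def five_record_vcf(tmp_path):
    path = tmp_path / "five.vcf"
    path.write_text(FIVE_RECORD_VCF)
    return path


@pytest.fixture
def region_1kb():
    return GenomicRegion("chr6", 0, 1000)


def make_reference(region: GenomicRegion, seed: int = 7) -> ReferenceTrack:
    import numpy as np

    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, region.length)])
    return ReferenceTrack(region=region, sequence=seq)
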