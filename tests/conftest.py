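import numpy as np
import pandas as pd
import pytest

from wildkin import GenotypeMatrix


def make_matrix(codes, samples=None, chrom="chr1", pos_step=1000):
    """GenotypeMatrix from a plain list-of-lists of codes (rows=samples)."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    samples = samples or [f"S{i + 1}" for i in range(n)]
    snps = pd.DataFrame(
        {
            "chrom": [chrom] * m,
            "pos": np.arange(1, m + 1) * pos_step,
            "ref": ["A"] * m,
            "alt": ["G"] * m,
        }
    )
    return GenotypeMatrix(samples, snps, codes)


def hwe_matrix(n, p, rng, f=0.0):
    """n individuals at SNPs with frequencies p, inbreeding f, unlinked."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    auto = rng.random((n, p.size)) < f
    a = rng.random((n, p.size)) < p
    b = np.where(auto, a, rng.random((n, p.size)) < p)
    return make_matrix((a.astype(int) + b.astype(int)))


@pytest.fixture
def rng():
    return np.random.default_rng(20160805)


@pytest.fixture
def toy_vcf(tmp_path):
    """Tiny hand-written VCF: 2 samples, 3 bi-allelic SNPs, one missing call,
    one multi-allelic record and one indel to be skipped."""
    text = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\t./.
chr1\t300\t.\tG\tA,T\t.\tPASS\t.\tGT\t1/2\t0/0
chr1\t400\t.\tT\tTA\t.\tPASS\t.\tGT\t0/1\t0/0
chr1\t500\t.\tG\tC\t.\tPASS\t.\tGT\t1/1\t0/1
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return path
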