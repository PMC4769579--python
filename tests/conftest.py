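import textwrap

import numpy as np
import pytest

from quartetscan.genotype_io import GenotypeMatrix, QuartetSpec

VCF_HEADER = textwrap.dedent("""\
    ##fileformat=VCFv4.2
    ##contig=<ID=scaf1,length=100000>
    ##contig=<ID=scaf2,length=100000>
    ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
    ##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
    """)


@pytest.fixture
def write_vcf_text(tmp_path):
    """Write a VCF from a list of record lines (plus sample names)."""

    def _write(records, samples=("s1", "s2"), name="test.vcf"):
        path = tmp_path / name
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        with open(path, "w") as fh:
            fh.write(VCF_HEADER)
            fh.write(cols + "\t".join(samples) + "\n")
            for rec in records:
                fh.write(rec + "\n")
        return str(path)

    return _write


def make_matrix(pos, dosages, chrom="chr1", samples=None, depths=None):
    """Small GenotypeMatrix from explicit dosage rows."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_sites, n_samples = dosages.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    pos = np.asarray(pos, dtype=np.int64)
    chroms = np.array([chrom] * n_sites, dtype=object) \
        if isinstance(chrom, str) else np.asarray(chrom, dtype=object)
    return GenotypeMatrix(
        chroms=chroms, pos=pos,
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["T"] * n_sites, dtype=object),
        dosages=dosages, samples=list(samples),
        depths=None if depths is None else np.asarray(depths, dtype=np.int32),
    )


@pytest.fixture
def quartet13():
    """4+4+4+1 quartet matching 13-sample matrices."""
    return QuartetSpec(
        tuple(f"P1_{i}" for i in range(4)),
        tuple(f"P2_{i}" for i in range(4)),
        tuple(f"P3_{i}" for i in range(4)),
        ("O_0",),
    )


def quartet_samples():
    return ([f"P1_{i}" for i in range(4)] + [f"P2_{i}" for i in range(4)]
            + [f"P3_{i}" for i in range(4)] + ["O_0"])
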