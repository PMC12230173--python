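import io

import numpy as np
import pytest
from hypothesis import settings

import hybriscan as hs

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


VCF_SMALL = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr1>
##contig=<ID=chr2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampleA\tsampleB
chr1\t300\t.\tG\tGA\t.\t.\t.\tGT:DP:AD\t1/1:25:0,25\t0/1:18:9,9
chr1\t100\t.\tA\tT\t.\t.\t.\tGT:DP:AD\t0/1:30:14,16\t0/0:22:22,0
chr2\t50\t.\tC\tA,T\t.\t.\t.\tGT:DP\t./.:0\t1|2:40
"""


@pytest.fixture
def small_table():
    """3-record, 2-sample table: SNP + INDEL + multiallelic with missing call."""
    return hs.parse_variants(io.StringIO(VCF_SMALL))


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale simulated dataset shared by read-only tests."""
    params = hs.SimulationParams(seed=11)
    truth = hs.sample_truth(params)
    table = hs.simulate_genotyping(truth, params)
    return params, truth, table


@pytest.fixture(scope="session")
def small_sim():
    """Small simulated dataset for faster structural tests."""
    params = hs.SimulationParams(
        n_loci_diag=600, n_loci_bg=400, n_genes=250, seed=5
    )
    truth = hs.sample_truth(params)
    table = hs.simulate_genotyping(truth, params)
    return params, truth, table


def make_table(genotypes, samples=None, alleles=("A", "T"), dp=None):
    """Hand-build a VariantTable from per-locus per-sample genotype pairs.

    ``genotypes``: list over loci of lists over samples of (a, b) pairs or
    None for missing. All loci share the given allele list on chr1.
    """
    L = len(genotypes)
    S = len(genotypes[0])
    if samples is None:
        samples = [f"s{j + 1}" for j in range(S)]
    loci = [
        hs.Locus(chrom="chr1", pos=100 * (i + 1), ref=alleles[0], alts=tuple(alleles[1:]))
        for i in range(L)
    ]
    gt = np.full((L, S, 2), hs.MISSING, dtype=np.int32)
    dparr = np.full((L, S), 10, dtype=np.int64)
    ad = np.full((L, S, len(alleles)), -1, dtype=np.int64)
    for i, row in enumerate(genotypes):
        for j, g in enumerate(row):
            if g is not None:
                gt[i, j] = sorted(g)
    if dp is not None:
        dparr[:] = np.asarray(dp)
    return hs.VariantTable(loci, samples, gt, dparr, ad)
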