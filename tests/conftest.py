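"""Shared fixtures: tiny hand-checkable panels and a canonical example site."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from svpanel import ClusterAssignment, GenotypeMatrix, SVRecord

# The canonical cluster-specific deletion: carriers and nonmissing genotype
# counts across 8 population clusters (1, 2, 1, 0, 2, 19, 0, 1 carriers out
# of 32, 31, 31, 30, 35, 53, 44, 30 nonmissing genotypes; cluster 6 holds
# 19/26 = 73% of the carriers).
WORKED_OBSERVED = np.array([1, 2, 1, 0, 2, 19, 0, 1])
WORKED_NONMISSING = np.array([32, 31, 31, 30, 35, 53, 44, 30])


@pytest.fixture
def worked_example():
    return WORKED_OBSERVED.copy(), WORKED_NONMISSING.copy()


@pytest.fixture
def worked_example_matrix():
    """A 1-site matrix + assignment reproducing the canonical counts."""
    labels = np.concatenate(
        [np.full(m, c + 1) for c, m in enumerate(WORKED_NONMISSING)]
    )
    n = labels.size  # 286, all nonmissing
    row = np.zeros(n)
    offset = 0
    for c, m in enumerate(WORKED_NONMISSING):
        row[offset : offset + WORKED_OBSERVED[c]] = 1.0
        offset += m
    matrix = make_matrix(row[None, :], starts=[53588484])
    assignment = ClusterAssignment(
        sample_ids=matrix.sample_ids, labels=labels, k=8
    )
    return matrix, assignment


def make_matrix(presence, chrom="Chr01", starts=None, svtype="DEL"):
    presence = np.asarray(presence, dtype=float)
    n_sites, n_samples = presence.shape
    starts = list(starts) if starts is not None else [
        1000 * (i + 1) for i in range(n_sites)
    ]
    positions = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites if isinstance(chrom, str) else list(chrom),
            "start": starts,
            "end": [s + 99 for s in starts],
            "svtype": [svtype] * n_sites,
        }
    )
    return GenotypeMatrix(
        site_ids=[f"site{i}" for i in range(n_sites)],
        sample_ids=[f"S{i:04d}" for i in range(n_samples)],
        presence=presence,
        positions=positions,
    )


def make_record(
    site_id="Chr01_100_600_DEL",
    chrom="Chr01",
    start=100,
    end=600,
    svtype="DEL",
    length=None,
    precise=True,
    pe=5,
    carriers=(1, 0, 0, 0),
    depths=None,
):
    carriers = np.asarray(carriers, dtype=np.int8)
    if depths is None:
        depths = np.full(carriers.size, 30, dtype=np.int64)
    if length is None and svtype in ("DEL", "DUP", "INV"):
        length = end - start + 1
    return SVRecord(
        site_id=site_id,
        chrom=chrom,
        start=start,
        end=end,
        svtype=svtype,
        length_bp=length,
        precise=precise,
        pe_support=pe,
        carriers=carriers,
        depths=depths,
    )


SV_VCF_FIXTURE = """\
##fileformat=VCFv4.2
##contig=<ID=Chr01,length=1000000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##INFO=<ID=END,Number=1,Type=Integer,Description="End">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length">
##INFO=<ID=PE,Number=1,Type=Integer,Description="PE support">
##INFO=<ID=PRECISE,Number=0,Type=Flag,Description="Precise">
##INFO=<ID=IMPRECISE,Number=0,Type=Flag,Description="Imprecise">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
Chr01\t100\tdel1\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=600;PE=5;PRECISE\tGT:DP\t0/1:9\t0/1:10\t0/0:30
Chr01\t2000\tdup1\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=2299;SVLEN=300;PE=6;PRECISE\tGT:DP\t1/1:25\t0/0:25\t./.:25
Chr01\t5000\tinv1\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=5999;PE=4;IMPRECISE\tGT:DP\t0/0:20\t0/1:20\t0/0:20
Chr01\t7000\tbnd1\tN\t<BND>\t.\tPASS\tSVTYPE=BND;PE=9;PRECISE\tGT:DP\t0/1:30\t0/0:30\t0/0:30
Chr01\t9000\todd1\tN\t<CNV>\t.\tPASS\tSVTYPE=WEIRD;END=9100;PE=9;PRECISE\tGT:DP\t0/1:30\t0/0:30\t0/0:30
"""


@pytest.fixture
def sv_vcf_path(tmp_path):
    path = tmp_path / "fixture.vcf"
    path.write_text(SV_VCF_FIXTURE)
    return str(path)


GFF3_FIXTURE = """\
##gff-version 3
Chr01\tsrc\tgene\t1000\t2000\t.\t+\t.\tID=geneA
Chr01\tsrc\tmRNA\t1000\t2000\t.\t+\t.\tID=mrnaA;Parent=geneA
Chr01\tsrc\tCDS\t1200\t1500\t.\t+\t0\tID=cdsA;Parent=mrnaA
Chr01\tsrc\tgene\t5000\t8000\t.\t-\t.\tID=geneB
Chr01\tsrc\tCDS\t5100\t5400\t.\t-\t0\tID=cdsB;Parent=geneB
Chr02\tsrc\tgene\t100\t900\t.\t+\t.\tID=geneC
Chr02\tsrc\texon\t100\t400\t.\t+\t.\tID=exC;Parent=geneC
Chr02\tsrc\tCDS\t150\t350\t.\t+\t0\tID=cdsC;Parent=geneC
Chr02\tsrc\tgene\t2000\t2500\t.\t+\t.\tID=geneD
Chr02\tsrc\tCDS\t2100\t2200\t.\t+\t0\tID=cdsD;Parent=geneD
"""


@pytest.fixture
def gff3_path(tmp_path):
    path = tmp_path / "genes.gff3"
    path.write_text(GFF3_FIXTURE)
    return str(path)
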