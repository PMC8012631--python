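"""Shared fixtures: compact builders for trio datasets and VCF text."""

from __future__ import annotations

import numpy as np
import pytest

from partho.genotype_io import GenotypeState, TrioDataset

M = int(GenotypeState.MISSING)


def make_dataset(
    gt,
    depth=None,
    samples=("mother", "off1", "off2"),
    chrom=None,
    pos=None,
    qual=None,
    info=None,
    ref=None,
    alt=None,
) -> TrioDataset:
    """Build a TrioDataset from a (sites x samples) genotype-code matrix."""
    gt = np.asarray(gt, dtype=np.int8)
    n, s = gt.shape
    samples = list(samples)[:s]
    if depth is None:
        depth = np.full((n, s), 20)
    if chrom is None:
        chrom = ["chr1"] * n
    if pos is None:
        pos = list(range(100, 100 + 10 * n, 10))
    if qual is None:
        qual = [60.0] * n
    if info is None:
        info = [{} for _ in range(n)]
    if ref is None:
        ref = ["A"] * n
    if alt is None:
        alt = [("T",)] * n
    return TrioDataset(samples=samples, chrom=chrom, pos=pos, ref=ref, alt=alt,
                       qual=qual, info=info, gt=gt, depth=np.asarray(depth))


@pytest.fixture
def trio_vcf_text() -> str:
    """A hand-written 3-sample, 5-record VCF (one multiallelic, one missing call)."""
    return "\n".join([
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=100000>",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tmomma\tkidA\tkidB",
        "chr1\t100\t.\tA\tT\t90\t.\tQD=20\tGT:DP\t0/1:30\t0/0:22\t1/1:18",
        "chr1\t200\t.\tG\tC\t80\t.\tQD=25\tGT:DP\t0/0:15\t0/1:12\t0/0:14",
        "chr1\t300\t.\tT\tA\t70\t.\t.\tGT:DP\t1/1:20\t./.:0\t1/1:25",
        "chr1\t400\t.\tC\tG,T\t60\t.\t.\tGT:DP\t0/1:18\t0/1:17\t0/0:21",
        "chr1\t500\t.\tA\tG\t50\t.\tQD=1\tGT:DP\t0/1:25\t0/1:28\t0/1:24",
    ]) + "\n"


@pytest.fixture
def trio_vcf(tmp_path, trio_vcf_text):
    path = tmp_path / "trio.vcf"
    path.write_text(trio_vcf_text)
    return path
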