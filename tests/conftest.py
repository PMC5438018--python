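"""Shared fixtures: tiny hand-built cohorts and on-disk artifacts."""

from __future__ import annotations

import textwrap

import numpy as np
import pandas as pd
import pytest

from hemiassoc import CohortConfig, Region, VariantCall
from hemiassoc.annotate import GeneModel

SMALL_REGION = Region("chr22", 18_400_394, 18_550_393)  # 150 kb slice


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """A fast-but-structured cohort: full group sizes, reduced locus count."""
    return CohortConfig(
        region=SMALL_REGION,
        mean_variants_per_sample=200.0,
        n_genes=8,
        seed=11,
    )


@pytest.fixture
def four_sample_manifest() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["s1", "s2", "s3", "s4"],
            "group": ["case", "case", "control", "control"],
            "age": [25.0, 19.0, 30.0, 17.0],
        }
    )


@pytest.fixture
def dialect_vcf(tmp_path):
    """Hand-written VCF exercising haploid/diploid/missing/multi-allelic GTs."""
    text = textwrap.dedent(
        """\
        ##fileformat=VCFv4.2
        ##INFO=<ID=POP_AF,Number=A,Type=Float,Description="pop AF">
        ##INFO=<ID=CALLER,Number=1,Type=String,Description="caller">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        ##contig=<ID=chr22,length=51304566>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3\ts4
        chr22\t18400500\t.\tG\tA\t99\t.\tPOP_AF=0.01;CALLER=snv\tGT\t1\t1\t1\t0
        chr22\t18400600\t.\tG\tA,T\t80\t.\tPOP_AF=0.01,0.02;CALLER=snv\tGT\t1\t2\t0\t2
        chr22\t18400700\t.\tC\tT\t70\t.\tCALLER=snv\tGT\t1/1\t0/1\t./.\t0/0
        chr22\t18300000\t.\tA\tG\t99\t.\tPOP_AF=0.2;CALLER=snv\tGT\t1\t0\t0\t0
        chr22\t18400800\t.\tAT\tA\t700\t.\tPOP_AF=0.001\tGT\t1\t0\t1\t0
        """
    )
    p = tmp_path / "dialect.vcf"
    p.write_text(text)
    return p


def make_call(pos=18_400_500, caller="snv", qual=99.0, pop_af=0.01,
              carriers=("s1", "s2"), ref="G", alt="A") -> VariantCall:
    return VariantCall(
        chrom="chr22", pos=pos, ref=ref, alt=alt, caller=caller,
        qual=qual, pop_af=pop_af, carriers=frozenset(carriers),
    )


@pytest.fixture
def toy_gene() -> GeneModel:
    """Two-exon plus-strand gene inside a 200 bp neighbourhood.

    exon1 = [100, 150], exon2 = [200, 260]; CDS trims 10 bp UTR off each
    terminal end: CDS = [110, 150] + [200, 250].  The intron [151, 199]
    carries 6 nt splice windows at both ends.
    """
    return GeneModel(
        gene_id="TOY1",
        strand="+",
        exons=((100, 150), (200, 260)),
        cds=((110, 150), (200, 250)),
    )


@pytest.fixture
def toy_gene_minus(toy_gene) -> GeneModel:
    """The same intervals on the minus strand (classification must match)."""
    return GeneModel(
        gene_id="TOY1M", strand="-", exons=toy_gene.exons, cds=toy_gene.cds
    )
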