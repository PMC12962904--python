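"""Shared fixtures: toy VCFs, pool counts, synthetic gene models."""

from __future__ import annotations

import numpy as np
import pytest

from bsascan.variant_io import PoolCounts, PooledVariant, SiteQC

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Strand bias">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##contig=<ID=chr01,length=10000000>
##contig=<ID=chr02,length=10000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tEP02\tEP01\tZS\tLS
"""

#: Role map matching the sample columns of :data:`VCF_HEADER`.
ROLE_MAP = {
    "EP02": "parent_purple",
    "EP01": "parent_green",
    "ZS": "bulk_purple",
    "LS": "bulk_green",
}


def write_vcf_text(path, records: list[str]) -> str:
    """Write a toy VCF from pre-formatted record lines."""
    path.write_text(VCF_HEADER + "".join(r.rstrip("\n") + "\n" for r in records))
    return str(path)


def vcf_record(
    chrom="chr01", pos=100, ref="A", alt="G", qual=100.0,
    dp=200, mq=60.0, qd=25.0, fs=2.0, an=8, sor=1.0,
    ads=((30, 0), (0, 30), (28, 2), (1, 29)),
) -> str:
    """One VCF record line with AD per sample (EP02, EP01, ZS, LS order)."""
    info = f"DP={dp};MQ={mq};QD={qd};FS={fs};AN={an};SOR={sor}"
    samples = "\t".join(f"./.:{r},{a}" for r, a in ads)
    return f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\tPASS\t{info}\tGT:AD\t{samples}"


def make_variant(
    chrom="chr01", pos=100, ref="A", alt="G",
    green=(10, 30), purple=(30, 10),
    parent_purple=(0, 40), parent_green=(40, 0),
    qc: SiteQC | None = None,
) -> PooledVariant:
    """A PooledVariant from (ref, alt) depth pairs per role."""
    return PooledVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt,
        qc=qc or SiteQC(dp=200.0, qual=100.0, mq=60.0, qd=25.0, fs=2.0, an=8.0, sor=1.0),
        counts_by_sample={
            "parent_purple": PoolCounts(*parent_purple),
            "parent_green": PoolCounts(*parent_green),
            "bulk_purple": PoolCounts(*purple),
            "bulk_green": PoolCounts(*green),
        },
    )


def pc(ref: int, alt: int) -> PoolCounts:
    return PoolCounts(ref_depth=ref, alt_depth=alt)


# ---------------------------------------------------------------------------
# synthetic annotation fixtures

GFF_HEADER = "##gff-version 3\n"


def gene_gff3_lines(gene_id, chrom, strand, gene_span, exons, cds, description=""):
    """GFF3 lines for one gene with a single mRNA."""
    attrs = f"ID={gene_id}"
    if description:
        attrs += f";description={description}"
    lines = [
        f"{chrom}\t.\tgene\t{gene_span[0]}\t{gene_span[1]}\t.\t{strand}\t.\t{attrs}",
        f"{chrom}\t.\tmRNA\t{gene_span[0]}\t{gene_span[1]}\t.\t{strand}\t.\t"
        f"ID={gene_id}.t1;Parent={gene_id}",
    ]
    for i, (s, e) in enumerate(exons):
        lines.append(
            f"{chrom}\t.\texon\t{s}\t{e}\t.\t{strand}\t.\t"
            f"ID={gene_id}.e{i};Parent={gene_id}.t1"
        )
    for i, (s, e) in enumerate(cds):
        lines.append(
            f"{chrom}\t.\tCDS\t{s}\t{e}\t.\t{strand}\t0\t"
            f"ID={gene_id}.c{i};Parent={gene_id}.t1"
        )
    return lines


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def toy_genome():
    """200 kb single-chromosome genome with two genes (one per strand).

    geneA (+): 10,001-13,000; exons 10,001-11,000 and 12,001-13,000;
    CDS 10,201-11,000 + 12,001-12,400 (1200 bp).  UTRs: 10,001-10,200
    (5') and 12,401-13,000 (3').
    geneB (-): 50,001-52,000; single exon = CDS 50,101-51,900 (1800 bp);
    UTRs 51,901-52,000 (5', minus strand) and 50,001-50,100 (3').
    """
    rng = np.random.default_rng(2024)
    seq = random_sequence(rng, 200_000)
    gff = GFF_HEADER + "\n".join(
        gene_gff3_lines(
            "geneA", "chrT", "+", (10_001, 13_000),
            exons=[(10_001, 11_000), (12_001, 13_000)],
            cds=[(10_201, 11_000), (12_001, 12_400)],
            description="plus-strand two-exon gene",
        )
        + gene_gff3_lines(
            "geneB", "chrT", "-", (50_001, 52_000),
            exons=[(50_001, 52_000)],
            cds=[(50_101, 51_900)],
            description="minus-strand single-exon gene",
        )
    ) + "\n"
    return {"chrT": seq}, gff


@pytest.fixture(scope="session")
def toy_gene_models(toy_genome, tmp_path_factory):
    from bsascan.annotation import load_gene_models

    genome, gff = toy_genome
    gff_path = tmp_path_factory.mktemp("ann") / "toy.gff3"
    gff_path.write_text(gff)
    return load_gene_models(gff_path, genome), genome


@pytest.fixture(scope="session")
def default_experiment():
    """One default synthetic experiment shared across tests (seed 7)."""
    from bsascan.simulate import simulate_experiment

    return simulate_experiment(seed=7)
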