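"""Gene-context annotation of candidate SNPs.

Assigns each SNP one of the effect categories used in BSA candidate
reports — EXON:SYNONYMOUS_CODING, EXON:NON_SYNONYMOUS_CODING, INTRON,
UTR_5_PRIME, UTR_3_PRIME, UPSTREAM, DOWNSTREAM, INTERGENIC — against
GFF3 gene models and a reference FASTA, and builds the candidate-SNP
table for a consensus QTL interval.

Only the canonical (longest-CDS) transcript per gene is used.  Coding
effects assume a complete CDS (total length divisible by 3, frame 0 at
the first codon); genes violating the model invariants are skipped with
a log message rather than guessed at.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

from .intervals import QTLInterval
from .variant_io import PooledVariant

logger = logging.getLogger(__name__)

CATEGORIES = (
    "EXON:NON_SYNONYMOUS_CODING",
    "EXON:SYNONYMOUS_CODING",
    "UTR_5_PRIME",
    "UTR_3_PRIME",
    "INTRON",
    "UPSTREAM",
    "DOWNSTREAM",
    "INTERGENIC",
)

#: Severity order used when a SNP falls in overlapping genes: coding
#: changes outrank UTR, UTR outranks intron, intron outranks flanking.
_SEVERITY = {
    "EXON:NON_SYNONYMOUS_CODING": 0,
    "EXON:SYNONYMOUS_CODING": 1,
    "UTR_5_PRIME": 2,
    "UTR_3_PRIME": 2,
    "INTRON": 3,
    "UPSTREAM": 4,
    "DOWNSTREAM": 4,
    "INTERGENIC": 5,
}


@dataclass(frozen=True)
class GeneModel:
    """One gene's canonical transcript: spans are 1-based inclusive."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]
    description: str = ""

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def cds_span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]


@dataclass(frozen=True)
class SnpEffect:
    """Effect of one SNP relative to one gene (or intergenic)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    category: str
    aa_change: str | None = None
    description: str = ""


class ReferenceMismatchError(ValueError):
    """VCF REF base disagrees with the reference FASTA."""


def _fetch(genome, chrom: str, start: int, end: int) -> str:
    """Reference sequence, 1-based inclusive, uppercased.

    ``genome`` is a ``pyfaidx.Fasta`` or any mapping of chromosome name
    to sequence string.
    """
    seq = genome[chrom]
    if isinstance(seq, str):
        return seq[start - 1 : end].upper()
    return str(seq[start - 1 : end]).upper()


def load_gene_models(gff3: str | Path, fasta: str | Path | Mapping[str, str]) -> list[GeneModel]:
    """Load canonical gene models from GFF3, validated against the FASTA.

    For each gene the transcript with the longest total CDS is kept.
    Genes are skipped (and logged) when they have no CDS, their CDS
    length is not divisible by 3, or exons/CDS violate containment.
    A GFF3 chromosome absent from the FASTA is an error.
    """
    genome = fasta if isinstance(fasta, Mapping) else Fasta(str(fasta))
    db = gffutils.create_db(
        str(gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome:
            raise ValueError(
                f"chromosome {gene.seqid!r} from GFF3 is missing from the FASTA"
            )
        best: tuple[int, tuple, tuple] | None = None
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = tuple(
                sorted((f.start, f.end) for f in db.children(mrna, featuretype="exon"))
            )
            cds = tuple(
                sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
            )
            cds_len = sum(e - s + 1 for s, e in cds)
            if best is None or cds_len > best[0]:
                best = (cds_len, exons, cds)
        if best is None or best[0] == 0:
            logger.info("skipping gene %s: no CDS", gene.id)
            continue
        cds_len, exons, cds = best
        if cds_len % 3 != 0:
            logger.info("skipping gene %s: CDS length %d not divisible by 3", gene.id, cds_len)
            continue
        if exons and (exons[0][0] < gene.start or exons[-1][1] > gene.end):
            logger.info("skipping gene %s: exons outside gene span", gene.id)
            continue
        if exons and not all(
            any(es <= cs and ce <= ee for es, ee in exons) for cs, ce in cds
        ):
            logger.info("skipping gene %s: CDS not contained in exons", gene.id)
            continue
        desc = gene.attributes.get("description", [""])[0]
        models.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons or cds,
                cds=cds,
                description=desc,
            )
        )
    models.sort(key=lambda g: (g.chrom, g.start, g.end))
    return models


def coding_effect(variant: PooledVariant, gene: GeneModel, genome) -> SnpEffect:
    """Synonymous/non-synonymous call for a SNP inside a gene's CDS.

    Builds the reference codon strand-aware (CDS segments concatenated
    in transcription order, reverse-complemented on the minus strand),
    substitutes the ALT base and translates both with the standard
    nuclear code.  ``aa_change`` is formatted refAA/codonNumber/altAA.
    """
    pos = variant.pos
    segs = gene.cds if gene.strand == "+" else tuple(reversed(gene.cds))
    offset = 0
    for s, e in segs:
        if s <= pos <= e:
            offset += (pos - s) if gene.strand == "+" else (e - pos)
            break
        offset += e - s + 1
    else:
        raise ValueError(f"{variant.chrom}:{pos} is not inside the CDS of {gene.gene_id}")

    genome_ref = _fetch(genome, gene.chrom, pos, pos)
    if genome_ref != variant.ref.upper():
        raise ReferenceMismatchError(
            f"{variant.chrom}:{pos}: VCF REF {variant.ref} != FASTA {genome_ref}"
        )

    cds_seq = "".join(_fetch(genome, gene.chrom, s, e) for s, e in gene.cds)
    if gene.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
    codon_idx = offset // 3
    within = offset % 3
    codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
    alt_base = variant.alt.upper()
    if gene.strand == "-":
        alt_base = str(Seq(alt_base).reverse_complement())
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    category = (
        "EXON:SYNONYMOUS_CODING" if ref_aa == alt_aa else "EXON:NON_SYNONYMOUS_CODING"
    )
    return SnpEffect(
        chrom=variant.chrom, pos=pos, ref=variant.ref, alt=variant.alt,
        gene_id=gene.gene_id, category=category,
        aa_change=f"{ref_aa}/{codon_idx + 1}/{alt_aa}",
        description=gene.description,
    )


def _effect_within_gene(variant: PooledVariant, gene: GeneModel, genome) -> SnpEffect:
    pos = variant.pos
    if any(s <= pos <= e for s, e in gene.cds):
        return coding_effect(variant, gene, genome)
    if any(s <= pos <= e for s, e in gene.exons):
        cds_start, cds_end = gene.cds_span
        if gene.strand == "+":
            category = "UTR_5_PRIME" if pos < cds_start else "UTR_3_PRIME"
        else:
            category = "UTR_5_PRIME" if pos > cds_end else "UTR_3_PRIME"
    else:
        category = "INTRON"
    return SnpEffect(
        chrom=variant.chrom, pos=pos, ref=variant.ref, alt=variant.alt,
        gene_id=gene.gene_id, category=category, description=gene.description,
    )


def classify_variant_location(
    variant: PooledVariant,
    genes: Sequence[GeneModel],
    genome=None,
    flank: int = 5000,
) -> SnpEffect:
    """Single effect category for a SNP: genic, flanking or intergenic.

    Inside a gene: CDS -> EXON:* (needs ``genome``), exon-not-CDS ->
    UTR_5/3_PRIME strand-aware, otherwise INTRON.  Within ``flank`` bp
    of a gene: UPSTREAM/DOWNSTREAM strand-aware.  Otherwise INTERGENIC.
    When several genes apply, the most severe category wins; the nearest
    gene breaks flanking ties.
    """
    pos = variant.pos
    containing = [
        g for g in genes if g.chrom == variant.chrom and g.start <= pos <= g.end
    ]
    if containing:
        effects = [_effect_within_gene(variant, g, genome) for g in containing]
        return min(effects, key=lambda e: _SEVERITY[e.category])

    best: tuple[int, SnpEffect] | None = None
    for g in genes:
        if g.chrom != variant.chrom:
            continue
        if g.start - flank <= pos < g.start:
            dist = g.start - pos
            category = "UPSTREAM" if g.strand == "+" else "DOWNSTREAM"
        elif g.end < pos <= g.end + flank:
            dist = pos - g.end
            category = "DOWNSTREAM" if g.strand == "+" else "UPSTREAM"
        else:
            continue
        eff = SnpEffect(
            chrom=variant.chrom, pos=pos, ref=variant.ref, alt=variant.alt,
            gene_id=g.gene_id, category=category, description=g.description,
        )
        if best is None or dist < best[0]:
            best = (dist, eff)
    if best is not None:
        return best[1]
    return SnpEffect(
        chrom=variant.chrom, pos=pos, ref=variant.ref, alt=variant.alt,
        gene_id=None, category="INTERGENIC",
    )


def annotate_variants(
    variants: Iterable[PooledVariant],
    genes: Sequence[GeneModel],
    genome,
    flank: int = 5000,
) -> list[SnpEffect]:
    """Classify every variant; one effect per variant (most severe gene wins)."""
    return [classify_variant_location(v, genes, genome, flank) for v in variants]


def build_candidate_table(
    effects: Sequence[SnpEffect],
    site_stats: pd.DataFrame,
    interval: QTLInterval,
) -> pd.DataFrame:
    """Candidate-SNP report for one consensus interval.

    Rows are the annotated SNPs inside the interval, joined with their
    ΔSNP-index and ED⁴, sorted by descending |Δ| then descending ED⁴
    (signed Δ is kept in the table).
    """
    eff = pd.DataFrame(
        [
            {
                "chrom": e.chrom, "pos": e.pos, "ref": e.ref, "alt": e.alt,
                "type": e.category, "gene_id": e.gene_id or "",
                "aa_change": e.aa_change or "", "description": e.description,
            }
            for e in effects
        ]
    )
    if eff.empty:
        return pd.DataFrame(
            columns=["chrom", "pos", "delta_snp_index", "ed4", "ref", "alt",
                     "type", "gene_id", "aa_change", "description"]
        )
    stats = site_stats[["chrom", "pos", "delta", "ed4"]].rename(
        columns={"delta": "delta_snp_index"}
    )
    table = eff.merge(stats, on=["chrom", "pos"], how="left")
    table = table[
        (table["chrom"] == interval.chrom)
        & (table["pos"] >= interval.start)
        & (table["pos"] <= interval.end)
    ].copy()
    table["_abs_delta"] = table["delta_snp_index"].abs()
    table = table.sort_values(
        ["_abs_delta", "ed4", "pos"], ascending=[False, False, True]
    ).drop(columns="_abs_delta")
    return table[
        ["chrom", "pos", "delta_snp_index", "ed4", "ref", "alt", "type",
         "gene_id", "aa_change", "description"]
    ].reset_index(drop=True)
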