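"""Pooled-VCF input and site-level quality filtering.

Reads biallelic SNPs with per-sample allele depths (AD) from a four-sample
VCF — two inbred parental pools and two extreme-phenotype bulks — into the
package's internal variant model, applies GATK-style hard filters on site
metrics, and restricts to parent-informative sites (parents effectively
homozygous for opposite alleles).

Coordinates are 1-based inclusive throughout (VCF convention); BED exports
convert to 0-based half-open.
"""

from __future__ import annotations

import logging
import math
from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from cyvcf2 import VCF

logger = logging.getLogger(__name__)

#: Sample roles the pipeline requires.  ``parent_purple``/``parent_green``
#: are the two inbred parental pools; ``bulk_purple``/``bulk_green`` the
#: extreme-phenotype F2 bulks.
ROLES = ("parent_purple", "parent_green", "bulk_purple", "bulk_green")


class VcfConfigError(ValueError):
    """Raised when the sample-role mapping does not match the VCF."""


class VcfOrderError(ValueError):
    """Raised when VCF records are not (chrom, pos) sorted."""


@dataclass(frozen=True)
class PoolCounts:
    """Reference/alternate read depths of one pool at one site."""

    ref_depth: int
    alt_depth: int

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("read depths must be non-negative")

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth


@dataclass(frozen=True)
class SiteQC:
    """Site-level quality metrics used by the hard filters.

    ``None`` marks a metric absent from the record, which is distinct from
    a value of zero.
    """

    dp: float | None = None
    qual: float | None = None
    mq: float | None = None
    qd: float | None = None
    fs: float | None = None
    an: float | None = None
    sor: float | None = None


@dataclass(frozen=True)
class PooledVariant:
    """One biallelic SNP with per-pool allele depths."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    qc: SiteQC = field(default_factory=SiteQC)
    counts_by_sample: Mapping[str, PoolCounts] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("REF and ALT must differ")

    def counts(self, role: str) -> PoolCounts:
        return self.counts_by_sample[role]


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter cutoffs on site metrics.

    Defaults are the conventional GATK-style cutoffs for pooled
    resequencing at ~45x per sample: site depth (summed over the four
    samples) within [60, 1000], QUAL >= 50, MQ >= 50, QD >= 2, FS <= 40,
    AN >= 5 and SOR <= 5.  Boundary values pass.
    """

    dp_min: float = 60.0
    dp_max: float = 1000.0
    qual_min: float = 50.0
    mq_min: float = 50.0
    qd_min: float = 2.0
    fs_max: float = 40.0
    an_min: float = 5.0
    sor_max: float = 5.0

    def __post_init__(self) -> None:
        if not self.dp_min < self.dp_max:
            raise ValueError("dp_min must be < dp_max")


#: Filter rules in evaluation order; an excluded record is attributed to
#: the first violated rule.  Each entry: (rule name, qc attribute,
#: predicate(value, thresholds) -> passes).
_FILTER_RULES = (
    ("DP", "dp", lambda v, t: t.dp_min <= v <= t.dp_max),
    ("QUAL", "qual", lambda v, t: v >= t.qual_min),
    ("MQ", "mq", lambda v, t: v >= t.mq_min),
    ("QD", "qd", lambda v, t: v >= t.qd_min),
    ("FS", "fs", lambda v, t: v <= t.fs_max),
    ("AN", "an", lambda v, t: v >= t.an_min),
    ("SOR", "sor", lambda v, t: v <= t.sor_max),
)


def _info_float(variant, key: str) -> float | None:
    value = variant.INFO.get(key)
    if value is None:
        return None
    try:
        value = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(value) else value


def read_pooled_vcf(
    path: str | Path,
    sample_roles: Mapping[str, str],
) -> list[PooledVariant]:
    """Read biallelic SNPs from a four-sample pooled VCF.

    Parameters
    ----------
    path
        VCF v4.x file (plain or bgzipped) with a per-sample ``AD``
        FORMAT field.
    sample_roles
        Mapping of VCF sample name to role; all four roles in
        :data:`ROLES` must appear exactly once.

    Returns
    -------
    list of :class:`PooledVariant` in (chrom, pos) order.  Multiallelic
    records, non-SNP records and records without usable AD are skipped and
    counted in the log.

    Raises
    ------
    VcfConfigError
        If the role map is incomplete or names samples absent from the VCF.
    VcfOrderError
        If records are not sorted, naming the offending record.
    """
    assigned = sorted(sample_roles.values())
    if assigned != sorted(ROLES):
        raise VcfConfigError(
            f"sample_roles must assign each of {ROLES} exactly once, got {assigned}"
        )

    vcf = VCF(str(path))
    vcf_samples = list(vcf.samples)
    missing = [s for s in sample_roles if s not in vcf_samples]
    if missing:
        raise VcfConfigError(f"samples {missing} not present in VCF {path}")
    role_by_index = {vcf_samples.index(name): role for name, role in sample_roles.items()}

    variants: list[PooledVariant] = []
    skipped = {"multiallelic": 0, "non_snp": 0, "missing_ad": 0}
    last: tuple[str, int] | None = None
    seen_chroms: set[str] = set()

    for rec in vcf:
        key = (rec.CHROM, rec.POS)
        if last is not None:
            if rec.CHROM == last[0]:
                if rec.POS < last[1]:
                    raise VcfOrderError(
                        f"unsorted VCF: {rec.CHROM}:{rec.POS} after {last[0]}:{last[1]}"
                    )
            elif rec.CHROM in seen_chroms:
                raise VcfOrderError(
                    f"unsorted VCF: chromosome {rec.CHROM} re-appears at position {rec.POS}"
                )
        seen_chroms.add(rec.CHROM)
        last = key

        if len(rec.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        if not rec.is_snp:
            skipped["non_snp"] += 1
            continue

        ad = rec.format("AD")
        if ad is None:
            skipped["missing_ad"] += 1
            continue
        counts: dict[str, PoolCounts] = {}
        ok = True
        for idx, role in role_by_index.items():
            ref_d, alt_d = int(ad[idx][0]), int(ad[idx][1])
            if ref_d < 0 or alt_d < 0:  # cyvcf2 encodes missing AD as negatives
                ok = False
                break
            counts[role] = PoolCounts(ref_depth=ref_d, alt_depth=alt_d)
        if not ok:
            skipped["missing_ad"] += 1
            continue

        qc = SiteQC(
            dp=_info_float(rec, "DP"),
            qual=None if rec.QUAL is None else float(rec.QUAL),
            mq=_info_float(rec, "MQ"),
            qd=_info_float(rec, "QD"),
            fs=_info_float(rec, "FS"),
            an=_info_float(rec, "AN"),
            sor=_info_float(rec, "SOR"),
        )
        variants.append(
            PooledVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=rec.ALT[0],
                qc=qc,
                counts_by_sample=counts,
            )
        )
    vcf.close()

    n_skipped = sum(skipped.values())
    if n_skipped:
        logger.info("read_pooled_vcf: skipped %d records (%s)", n_skipped, skipped)
    return variants


def apply_quality_filters(
    variants: Iterable[PooledVariant],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[PooledVariant], "OrderedDict[str, int]"]:
    """Apply hard site filters; return retained variants and removal counts.

    A variant is retained iff every metric passes its cutoff (boundary
    values pass).  A missing metric fails its rule: the filters select
    highly reliable variants, so absence of evidence excludes.  Removal
    counts attribute each excluded record to the first violated rule in
    the order DP, QUAL, MQ, QD, FS, AN, SOR.
    """
    thresholds = thresholds or FilterThresholds()
    removed: "OrderedDict[str, int]" = OrderedDict((name, 0) for name, _, _ in _FILTER_RULES)
    retained: list[PooledVariant] = []
    for v in variants:
        failed = None
        for name, attr, passes in _FILTER_RULES:
            value = getattr(v.qc, attr)
            if value is None or not passes(value, thresholds):
                failed = name
                break
        if failed is None:
            retained.append(v)
        else:
            removed[failed] += 1
    return retained, removed


def select_informative_snps(
    variants: Iterable[PooledVariant],
    min_parent_depth: int = 10,
    max_minor_fraction: float = 0.05,
) -> list[PooledVariant]:
    """Keep sites where the parents are fixed for opposite alleles.

    A site is parent-informative when each parental pool has
    ``total_depth >= min_parent_depth``, each parent's minor-allele read
    fraction is ``<= max_minor_fraction`` (effective homozygosity), and
    the two parents' major alleles differ.
    """
    out: list[PooledVariant] = []
    for v in variants:
        try:
            p1 = v.counts("parent_purple")
            p2 = v.counts("parent_green")
        except KeyError:
            continue
        if p1.total_depth < min_parent_depth or p2.total_depth < min_parent_depth:
            continue
        f1 = p1.alt_depth / p1.total_depth
        f2 = p2.alt_depth / p2.total_depth
        if min(f1, 1 - f1) > max_minor_fraction or min(f2, 1 - f2) > max_minor_fraction:
            continue
        if (f1 >= 0.5) == (f2 >= 0.5):  # same major allele -> not segregating
            continue
        out.append(v)
    return out


def write_variant_table(variants: Sequence[PooledVariant], path: str | Path) -> None:
    """Write a TSV of chrom, pos, ref, alt and per-pool ref/alt depths."""
    cols = [f"{role}_{which}" for role in ROLES for which in ("ref", "alt")]
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\t" + "\t".join(cols) + "\n")
        for v in variants:
            depths = []
            for role in ROLES:
                c = v.counts(role)
                depths += [str(c.ref_depth), str(c.alt_depth)]
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t" + "\t".join(depths) + "\n")


def write_filter_log(removed: Mapping[str, int], path: str | Path) -> None:
    """Write per-rule removal counts as a two-column TSV."""
    with open(path, "w") as fh:
        fh.write("rule\tn_removed\n")
        for rule, n in removed.items():
            fh.write(f"{rule}\t{n}\n")
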