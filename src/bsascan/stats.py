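"""Per-site BSA statistics and the Mendelian segregation test.

The two association statistics compare allele frequencies between the
green-phenotype and purple-phenotype bulks at each biallelic SNP:

* SNP-index — the fraction of reads carrying the alternate allele in one
  pool, ``alt / (alt + ref)``.
* ΔSNP-index — SNP-index of the green bulk minus SNP-index of the purple
  bulk.  Near ±1 at markers tightly linked to the causal locus, near 0
  elsewhere; the sign depends on which parent carries the ALT allele, so
  thresholding downstream uses |Δ| while reports keep the sign.
* ED / ED⁴ — the Euclidean distance between the two bulks' allele
  frequency vectors, ``sqrt(Δf_alt² + Δf_ref²)``, raised to the fourth
  power to suppress background noise.  For a biallelic site
  Δf_ref = −Δf_alt, so ED = √2·|Δf_alt| and ED⁴ = 4·Δf_alt⁴ with a
  maximum of 4 at opposite fixation.

Sites with zero depth in a pool are undefined (NaN), never imputed:
pseudocounts would distort the extreme-frequency identities that make the
statistics interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .variant_io import PoolCounts, PooledVariant


def snp_index(counts: PoolCounts) -> float:
    """Alternate-allele read fraction of one pool; NaN at zero depth."""
    if counts.total_depth == 0:
        return float("nan")
    return counts.alt_depth / counts.total_depth


def delta_snp_index(green: PoolCounts, purple: PoolCounts) -> float:
    """SNP-index(green bulk) − SNP-index(purple bulk); NaN if either side is undefined."""
    return snp_index(green) - snp_index(purple)


def ed(green: PoolCounts, purple: PoolCounts) -> float:
    """Euclidean distance between the bulks' (f_alt, f_ref) vectors.

    For a biallelic site Δf_ref = −Δf_alt exactly, so the distance is
    computed as √2·|Δf_alt| (algebraically identical to
    sqrt(Δf_alt² + Δf_ref²) and numerically stable at small Δ);
    range [0, √2].
    """
    fg = snp_index(green)
    fp = snp_index(purple)
    return float(np.sqrt(2.0) * abs(fg - fp))


def ed4(green: PoolCounts, purple: PoolCounts) -> float:
    """Fourth power of :func:`ed`; 4·Δf_alt⁴ for biallelic sites, range [0, 4]."""
    return ed(green, purple) ** 4


@dataclass(frozen=True)
class SegregationResult:
    """Pearson goodness-of-fit of phenotype class counts to a Mendelian ratio."""

    observed: tuple[int, ...]
    expected_ratio: tuple[float, ...]
    chi2: float
    df: int
    p_value: float


def segregation_chi_square(
    observed: Sequence[int],
    ratio: Sequence[float] = (1, 2, 1),
) -> SegregationResult:
    """Pearson χ² goodness-of-fit of class counts against a segregation ratio.

    Expected counts are ``total * weight / sum(weights)``; df is
    ``len(observed) - 1``; no continuity correction.

    >>> r = segregation_chi_square([177, 325, 144])
    >>> round(r.chi2, 2), round(r.p_value, 2)
    (3.4, 0.18)
    """
    obs = np.asarray(observed, dtype=float)
    weights = np.asarray(ratio, dtype=float)
    if obs.shape != weights.shape:
        raise ValueError("observed and ratio must have the same length")
    if (obs < 0).any() or (weights <= 0).any():
        raise ValueError("counts must be >= 0 and ratio weights > 0")
    total = obs.sum()
    if total == 0:
        raise ValueError("total count must be positive")
    expected = total * weights / weights.sum()
    chi2, p = sps.chisquare(obs, expected)
    return SegregationResult(
        observed=tuple(int(x) for x in obs),
        expected_ratio=tuple(float(w) for w in weights),
        chi2=float(chi2),
        df=len(obs) - 1,
        p_value=float(p),
    )


def site_stats(variants: Iterable[PooledVariant]) -> pd.DataFrame:
    """Vectorised per-site statistics track.

    Returns a DataFrame with one row per variant: chrom, pos, ref, alt,
    the four pools' ref/alt depths, snp_index of each bulk,
    delta (green − purple), ed, ed4 and bulk_mean_depth (mean of the two
    bulks' total depths, used to match simulation-null depths to windows).
    Undefined statistics are NaN.
    """
    rows = []
    for v in variants:
        bg = v.counts("bulk_green")
        bp = v.counts("bulk_purple")
        pg = v.counts("parent_green")
        pp = v.counts("parent_purple")
        rows.append(
            (
                v.chrom, v.pos, v.ref, v.alt,
                pp.ref_depth, pp.alt_depth, pg.ref_depth, pg.alt_depth,
                bp.ref_depth, bp.alt_depth, bg.ref_depth, bg.alt_depth,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt",
            "parent_purple_ref", "parent_purple_alt",
            "parent_green_ref", "parent_green_alt",
            "bulk_purple_ref", "bulk_purple_alt",
            "bulk_green_ref", "bulk_green_alt",
        ],
    )
    tot_g = df["bulk_green_ref"] + df["bulk_green_alt"]
    tot_p = df["bulk_purple_ref"] + df["bulk_purple_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        fg = np.where(tot_g > 0, df["bulk_green_alt"] / tot_g, np.nan)
        fp = np.where(tot_p > 0, df["bulk_purple_alt"] / tot_p, np.nan)
    df["snp_index_bulk_green"] = fg
    df["snp_index_bulk_purple"] = fp
    df["delta"] = fg - fp
    df["ed"] = np.sqrt(2.0) * np.abs(df["delta"])
    df["ed4"] = df["ed"] ** 4
    df["bulk_mean_depth"] = (tot_g + tot_p) / 2.0
    return df


def write_site_stats(df: pd.DataFrame, path) -> None:
    """Write the per-site statistics track as TSV."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
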