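"""Candidate-interval calling, intersection and reporting.

Flagged windows are merged into maximal runs (tolerating unflagged gaps
up to ``max_gap`` bp, default one window step so a single sparse window
cannot split a QTL), then boundaries are snapped to the first and last
significant raw SNP inside each run — the convention that makes interval
bounds coincide with real marker coordinates rather than window edges.
Intervals from the ΔSNP-index and ED⁴ scans are intersected into the
consensus QTL.

Width is reported as (end − start)/1e6 Mb (not +1); coordinates are
1-based inclusive, converted to 0-based half-open only in BED exports.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QTLInterval:
    """A candidate QTL region, 1-based inclusive."""

    chrom: str
    start: int
    end: int
    method: str  # "delta" | "ed4" | "consensus"
    n_supporting_snps: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


def interval_width_mb(interval: QTLInterval) -> float:
    """Physical width in megabases: (end − start)/1e6, unrounded.

    Report layers round to 2 d.p.; e.g. 59,315,357–76,806,837 -> 17.49 Mb.
    """
    return interval.width / 1e6


def call_intervals(
    windows: pd.DataFrame,
    flag_col: str,
    method: str,
    max_gap: int = 500_000,
    sig_snps: pd.DataFrame | None = None,
) -> list[QTLInterval]:
    """Merge flagged windows into intervals, snapping bounds to significant SNPs.

    Parameters
    ----------
    windows
        Window frame with chrom/start/end and a boolean ``flag_col``,
        sorted by (chrom, start).
    max_gap
        Maximal unflagged gap (bp) between consecutive flagged windows
        that is still bridged.
    sig_snps
        Optional frame of per-method significant raw SNPs (columns chrom,
        pos).  When given, each merged run's bounds are snapped to the
        first/last significant SNP it contains and
        ``n_supporting_snps`` counts them; runs containing none keep
        their window-edge bounds.
    """
    out: list[QTLInterval] = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        flagged = grp[grp[flag_col].astype(bool)]
        if flagged.empty:
            continue
        runs: list[list[int]] = []  # [start, end] per merged run
        for _, row in flagged.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if runs and s - runs[-1][1] - 1 <= max_gap:
                runs[-1][1] = max(runs[-1][1], e)
            else:
                runs.append([s, e])
        snp_pos = None
        if sig_snps is not None:
            snp_pos = np.sort(
                sig_snps.loc[sig_snps["chrom"] == chrom, "pos"].to_numpy(dtype=int)
            )
        for s, e in runs:
            n_sup = 0
            if snp_pos is not None and snp_pos.size:
                lo = np.searchsorted(snp_pos, s, side="left")
                hi = np.searchsorted(snp_pos, e, side="right")
                n_sup = int(hi - lo)
                if n_sup:
                    s, e = int(snp_pos[lo]), int(snp_pos[hi - 1])
            out.append(QTLInterval(chrom, s, e, method, n_sup))
    return out


def intersect_interval_sets(
    a: Iterable[QTLInterval],
    b: Iterable[QTLInterval],
    method: str = "consensus",
) -> list[QTLInterval]:
    """Pairwise positive overlaps (max of starts, min of ends) per chromosome."""
    out: list[QTLInterval] = []
    b = list(b)
    for ia in a:
        for ib in b:
            if ia.chrom != ib.chrom:
                continue
            s, e = max(ia.start, ib.start), min(ia.end, ib.end)
            if s <= e:
                out.append(
                    QTLInterval(
                        ia.chrom, s, e, method,
                        min(ia.n_supporting_snps, ib.n_supporting_snps),
                    )
                )
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def filter_consensus_by_joint_support(
    consensus: Iterable[QTLInterval],
    jointly_sig: pd.DataFrame,
) -> list[QTLInterval]:
    """Keep consensus intervals containing >= 1 SNP significant under both methods.

    ``jointly_sig`` has columns chrom, pos.  Guarantees every reported
    consensus QTL is anchored by at least one doubly-significant marker.
    """
    out = []
    for iv in consensus:
        pos = jointly_sig.loc[jointly_sig["chrom"] == iv.chrom, "pos"].to_numpy(dtype=int)
        n = int(((pos >= iv.start) & (pos <= iv.end)).sum())
        if n:
            out.append(replace(iv, n_supporting_snps=n))
    return out


def intervals_to_frame(intervals: Sequence[QTLInterval]) -> pd.DataFrame:
    """Tabulate intervals: chrom, start, end, width_mb, method, n_supporting_snps."""
    return pd.DataFrame(
        [
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "width_mb": round(interval_width_mb(iv), 2),
                "method": iv.method,
                "n_supporting_snps": iv.n_supporting_snps,
            }
            for iv in intervals
        ],
        columns=["chrom", "start", "end", "width_mb", "method", "n_supporting_snps"],
    )


def write_bed(intervals: Sequence[QTLInterval], path) -> None:
    """BED export: 0-based half-open, name = method."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.method}\n")
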