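"""Genome scan: sliding windows, LOESS smoothing and significance thresholds.

Per-site ΔSNP-index and ED⁴ tracks are aggregated into overlapping
sliding windows (default 1 Mb window, 500 kb step, anchored at position 1
of each chromosome), the window means are LOESS-smoothed per chromosome,
and two thresholds are computed:

* ED⁴ — the top 1% of per-SNP ED⁴ values genome-wide; windows whose
  fitted ED⁴ exceeds it are candidate windows.
* ΔSNP-index — a simulation null for the pooled design: each bulk's true
  allele frequency is the mean genotype dosage of ``bulk_size`` F2
  individuals drawn under Mendelian segregation, read counts are binomial
  at the observed depth, and the 95%/99% quantiles of |Δ| form the
  confidence interval.  Quantiles are tabulated on a depth grid and
  interpolated at each window's mean bulk depth.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

#: Depth grid on which null |Δ| quantiles are tabulated before
#: interpolation at observed window depths.
DEFAULT_DEPTH_GRID = (10, 20, 30, 45, 60, 90, 120, 200, 400, 1000)


@dataclass(frozen=True)
class ScanParams:
    """Scan configuration.

    window_size/step_size in bp (defaults 1 Mb / 500 kb); windows with
    fewer than ``min_snps_per_window`` SNPs carry undefined means and are
    excluded from thresholding; ``loess_span`` is the fraction of a
    chromosome's windows used per local fit; ``top_fraction`` sets the
    ED⁴ genome-wide threshold; ``ci_levels`` are the null |Δ| quantiles.
    """

    window_size: int = 1_000_000
    step_size: int = 500_000
    min_snps_per_window: int = 10
    loess_span: float = 0.1
    top_fraction: float = 0.01
    ci_levels: tuple[float, ...] = (0.95, 0.99)
    bulk_size: int = 30
    n_null_reps: int = 10_000

    def __post_init__(self) -> None:
        if self.step_size > self.window_size:
            raise ValueError("step_size must be <= window_size")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must lie in (0, 1)")


def make_windows(chrom_length: int, params: ScanParams) -> list[tuple[int, int]]:
    """Sliding windows over [1, chrom_length], 1-based inclusive.

    Starts at 1, 1+step, 1+2·step, …; a window is emitted iff its start
    is <= chrom_length and the final window is truncated at the
    chromosome end.
    """
    if chrom_length < 1:
        raise ValueError("chrom_length must be >= 1")
    out = []
    start = 1
    while start <= chrom_length:
        out.append((start, min(start + params.window_size - 1, chrom_length)))
        start += params.step_size
    return out


def window_scan(
    sites: pd.DataFrame,
    params: ScanParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Aggregate per-site statistics into sliding-window means.

    ``sites`` is a :func:`bsascan.stats.site_stats` frame sorted by
    (chrom, pos).  Chromosome lengths default to the last SNP position
    per chromosome.  Windows with fewer than ``min_snps_per_window``
    defined sites get NaN means.

    Returns one row per window: chrom, start, end, n_snps, mean_delta,
    mean_ed4, mean_depth.
    """
    params = params or ScanParams()
    rows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if not np.all(np.diff(pos) >= 0):
            raise ValueError(f"sites not position-sorted on {chrom}")
        length = (chrom_lengths or {}).get(chrom, int(pos.max()) if len(pos) else 1)
        delta = grp["delta"].to_numpy(dtype=float)
        ed4 = grp["ed4"].to_numpy(dtype=float)
        depth = grp["bulk_mean_depth"].to_numpy(dtype=float)
        defined = ~np.isnan(delta)
        for start, end in make_windows(length, params):
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            sel = defined[lo:hi]
            n = int(sel.sum())
            if n >= params.min_snps_per_window:
                md = float(np.mean(delta[lo:hi][sel]))
                me = float(np.mean(ed4[lo:hi][sel]))
                dep = float(np.mean(depth[lo:hi][sel]))
            else:
                md = me = dep = float("nan")
            rows.append((chrom, start, end, n, md, me, dep))
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "n_snps", "mean_delta", "mean_ed4", "mean_depth"],
    )


def loess_smooth(
    positions: Sequence[float],
    values: Sequence[float],
    span: float = 0.1,
) -> np.ndarray:
    """LOESS fit (degree 1, tricube weights) evaluated at the input positions.

    Smoothing is per-chromosome: call once per chromosome track.  NaN
    values are ignored for fitting and returned as NaN.  Fewer than 10
    defined points: the track is returned unsmoothed with a warning, as a
    local fit is not meaningful there.  The effective span is floored at
    3 points so every local regression is determined.
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~(np.isnan(positions) | np.isnan(values))
    n = int(ok.sum())
    out = np.full(values.shape, np.nan)
    if n < 10:
        warnings.warn(f"loess_smooth: only {n} defined points; returning values unsmoothed")
        out[ok] = values[ok]
        return out
    frac = min(1.0, max(span, 3.0 / n))
    fitted = lowess(values[ok], positions[ok], frac=frac, it=0, return_sorted=False)
    out[ok] = fitted
    return out


def top_fraction_threshold(values: Sequence[float], fraction: float = 0.01) -> float:
    """Empirical (1 − fraction) quantile with linear interpolation.

    NaNs are dropped first; an empty input is an error; fewer than
    1/fraction defined values triggers a warning (the extreme quantile is
    then poorly determined).
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("top_fraction_threshold: no defined values")
    if v.size < 1.0 / fraction:
        warnings.warn(
            f"top_fraction_threshold: only {v.size} values for fraction {fraction}"
        )
    return float(np.quantile(v, 1.0 - fraction))


@dataclass(frozen=True)
class NullCI:
    """Tabulated null quantiles of |Δ| for one pooled design.

    ``quantiles[level]`` is an array aligned with ``depth_grid``.
    """

    bulk_size: int
    population_type: str
    depth_grid: tuple[int, ...]
    quantiles: dict[float, np.ndarray]
    n_reps: int
    seed: int

    def at_depth(self, level: float, depth: float | np.ndarray) -> np.ndarray:
        """Quantile at arbitrary depth by linear interpolation on the grid."""
        return np.interp(depth, self.depth_grid, self.quantiles[level])


def simulate_delta_null(
    bulk_size: int,
    depth: int,
    population_type: str = "F2",
    n_reps: int = 10_000,
    ci_levels: Sequence[float] = (0.95, 0.99),
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[float, float]:
    """Null quantiles of |Δ| at a single depth.

    Each replicate draws each bulk's true alternate-allele frequency as
    the mean dosage/2 of ``bulk_size`` F2 individuals (dosage ~
    Binomial(2, 1/2), i.e. 0/1/2 with probability 1/4, 1/2, 1/4 under no
    linkage to the trait), then draws alt read counts ~ Binomial(depth,
    f) per bulk and records |Δ| of the read frequencies.
    """
    if population_type != "F2":
        raise ValueError(f"unknown population_type {population_type!r}; only 'F2' supported")
    if bulk_size < 1 or depth < 1:
        raise ValueError("bulk_size and depth must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    f = rng.binomial(2, 0.5, size=(n_reps, 2, bulk_size)).mean(axis=2) / 2.0
    reads = rng.binomial(depth, f) / depth
    abs_delta = np.abs(reads[:, 0] - reads[:, 1])
    return {float(q): float(np.quantile(abs_delta, q)) for q in ci_levels}


def null_ci_table(
    bulk_size: int,
    depth_grid: Sequence[int] = DEFAULT_DEPTH_GRID,
    population_type: str = "F2",
    n_reps: int = 10_000,
    ci_levels: Sequence[float] = (0.95, 0.99),
    seed: int = 0,
) -> NullCI:
    """Tabulate :func:`simulate_delta_null` quantiles across a depth grid."""
    rng = np.random.default_rng(seed)
    per_level: dict[float, list[float]] = {float(q): [] for q in ci_levels}
    for depth in depth_grid:
        qs = simulate_delta_null(
            bulk_size, int(depth), population_type, n_reps, ci_levels, rng=rng
        )
        for level, value in qs.items():
            per_level[level].append(value)
    return NullCI(
        bulk_size=bulk_size,
        population_type=population_type,
        depth_grid=tuple(int(d) for d in depth_grid),
        quantiles={level: np.asarray(v) for level, v in per_level.items()},
        n_reps=n_reps,
        seed=seed,
    )


def fit_ed4_track(sites: pd.DataFrame, span: float = 0.1) -> np.ndarray:
    """Per-SNP LOESS fit of the ED⁴ track, chromosome by chromosome.

    The ED⁴ method works at SNP resolution: candidate regions are where
    this fitted track exceeds the genome-wide top-fraction threshold of
    the raw per-SNP values.
    """
    fitted = np.full(len(sites), np.nan)
    for _, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        fitted[sites.index.get_indexer(idx)] = loess_smooth(
            grp["pos"].to_numpy(dtype=float), grp["ed4"].to_numpy(dtype=float), span
        )
    return fitted


def annotate_windows(
    windows: pd.DataFrame,
    sites: pd.DataFrame,
    params: ScanParams | None = None,
    null_ci: NullCI | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, NullCI, np.ndarray]:
    """Add fitted tracks, CI columns and significance flags to a window scan.

    Per chromosome the window means are LOESS-smoothed into
    ``fitted_delta`` and ``fitted_ed4``, and the per-SNP ED⁴ track is
    LOESS-fitted at SNP resolution.  ``ci95``/``ci99`` are null |Δ|
    quantiles interpolated at each window's mean depth.  Flags:

    * ``delta_flag`` — |fitted_delta| of the window exceeds the 95% null
      CI (the sliding-window ΔSNP-index method);
    * ``ed4_flag`` — the window overlaps a SNP whose LOESS-fitted ED⁴
      exceeds the genome-wide top-fraction threshold of raw per-SNP ED⁴
      values (the ED⁴ method, which is defined at SNP resolution).

    Returns the annotated window frame, the ED⁴ threshold, the tabulated
    :class:`NullCI` and the per-SNP fitted ED⁴ array aligned with
    ``sites``.
    """
    params = params or ScanParams()
    win = windows.copy()
    win["fitted_delta"] = np.nan
    win["fitted_ed4"] = np.nan
    for chrom, grp in win.groupby("chrom", sort=False):
        mid = (grp["start"] + grp["end"]) / 2.0
        win.loc[grp.index, "fitted_delta"] = loess_smooth(
            mid, grp["mean_delta"], params.loess_span
        )
        win.loc[grp.index, "fitted_ed4"] = loess_smooth(
            mid, grp["mean_ed4"], params.loess_span
        )

    if null_ci is None:
        null_ci = null_ci_table(
            bulk_size=params.bulk_size,
            n_reps=params.n_null_reps,
            ci_levels=params.ci_levels,
            seed=seed,
        )
    for level in params.ci_levels:
        col = f"ci{int(round(level * 100))}"
        win[col] = null_ci.at_depth(level, win["mean_depth"].to_numpy(dtype=float))

    ed4_threshold = top_fraction_threshold(sites["ed4"], params.top_fraction)
    ed4_fit = fit_ed4_track(sites, params.loess_span)
    ci95_col = f"ci{int(round(min(params.ci_levels) * 100))}"
    win["delta_flag"] = np.abs(win["fitted_delta"]) > win[ci95_col]

    hot = sites.loc[ed4_fit > ed4_threshold, ["chrom", "pos"]]
    ed4_flag = np.zeros(len(win), dtype=bool)
    for i, (_, row) in enumerate(win.iterrows()):
        sel = hot[hot["chrom"] == row["chrom"]]
        if not sel.empty:
            ed4_flag[i] = bool(
                ((sel["pos"] >= row["start"]) & (sel["pos"] <= row["end"])).any()
            )
    win["ed4_flag"] = ed4_flag
    win.loc[win["mean_delta"].isna(), ["delta_flag", "ed4_flag"]] = False
    return win, float(ed4_threshold), null_ci, ed4_fit
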