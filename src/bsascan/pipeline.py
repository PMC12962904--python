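"""End-to-end orchestration: variants -> statistics -> scan -> intervals -> report.

The analysis core (:func:`analyze_variants`) is pure in-memory and is
shared by the CLI, the simulation-recovery harness and the tests;
:func:`run_pipeline` wraps it with file IO, figures and the run summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import annotation as ann
from . import intervals as iv
from . import scan as sc
from . import simulate as sim
from . import stats as st
from . import variant_io as vio

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run.

    Exactly one of ``vcf`` (analyse existing calls) or ``simulate``
    (generate a synthetic experiment first) must be active.
    """

    vcf: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    phenotypes_csv: str | None = None
    sample_roles: dict[str, str] = field(
        default_factory=lambda: {v: k for k, v in sim.DEFAULT_SAMPLE_NAMES.items()}
    )
    simulate: bool = False
    sim_n: int = 646
    sim_bulk_size: int = 30
    sim_depth: float = 45.0
    sim_error_rate: float = 0.01
    sim_qtl_linked: bool = True
    thresholds: vio.FilterThresholds = field(default_factory=vio.FilterThresholds)
    scan_params: sc.ScanParams = field(default_factory=sc.ScanParams)
    max_gap: int = 500_000
    flank: int = 5000
    min_parent_depth: int = 10
    max_minor_fraction: float = 0.05
    out_dir: str = "bsascan_out"
    seed: int = 0
    make_plots: bool = True

    def validate(self) -> None:
        if self.simulate == bool(self.vcf):
            raise ValueError("exactly one of a VCF input or simulation mode must be set")


@dataclass
class AnalysisResult:
    """In-memory artifacts of one analysis."""

    sites: pd.DataFrame
    windows: pd.DataFrame
    ed4_threshold: float
    null_ci: sc.NullCI
    delta_intervals: list[iv.QTLInterval]
    ed4_intervals: list[iv.QTLInterval]
    consensus: list[iv.QTLInterval]
    delta_sig_snps: pd.DataFrame
    ed4_sig_snps: pd.DataFrame

    @property
    def top_consensus(self) -> iv.QTLInterval | None:
        if not self.consensus:
            return None
        return max(self.consensus, key=lambda x: x.n_supporting_snps)


def analyze_variants(
    variants: Sequence[vio.PooledVariant],
    params: sc.ScanParams | None = None,
    max_gap: int = 500_000,
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
) -> AnalysisResult:
    """Run the statistical core on filtered, parent-informative variants.

    Computes per-site ΔSNP-index and ED⁴, the sliding-window scan with
    LOESS-fitted tracks, the genome-wide ED⁴ top-fraction threshold and
    the simulation-null ΔSNP-index confidence interval, then calls
    per-method intervals and their consensus.  Consensus intervals must
    contain at least one SNP significant under both statistics.
    """
    params = params or sc.ScanParams()
    sites = st.site_stats(variants)
    windows = sc.window_scan(sites, params, chrom_lengths)
    win, ed4_thr, null_ci, ed4_fit = sc.annotate_windows(windows, sites, params, seed=seed)
    sites = sites.assign(ed4_fit=ed4_fit)

    ci_level = min(params.ci_levels)
    site_ci = null_ci.at_depth(ci_level, sites["bulk_mean_depth"].to_numpy(dtype=float))
    delta_sig = sites.loc[np.abs(sites["delta"].to_numpy()) >= site_ci, ["chrom", "pos"]]
    ed4_sig = sites.loc[sites["ed4"] >= ed4_thr, ["chrom", "pos"]]

    delta_iv = iv.call_intervals(win, "delta_flag", "delta", max_gap, delta_sig)
    ed4_iv = iv.call_intervals(win, "ed4_flag", "ed4", max_gap, ed4_sig)
    consensus = iv.intersect_interval_sets(delta_iv, ed4_iv)
    jointly = delta_sig.merge(ed4_sig, on=["chrom", "pos"])
    consensus = iv.filter_consensus_by_joint_support(consensus, jointly)
    return AnalysisResult(
        sites=sites,
        windows=win,
        ed4_threshold=ed4_thr,
        null_ci=null_ci,
        delta_intervals=delta_iv,
        ed4_intervals=ed4_iv,
        consensus=consensus,
        delta_sig_snps=delta_sig,
        ed4_sig_snps=ed4_sig,
    )


def _config_payload(config: RunConfig) -> dict:
    payload = dataclasses.asdict(config)
    return payload


def summarize_run(
    result: AnalysisResult,
    removed: Mapping[str, int],
    n_input: int,
    n_informative: int,
    segregation: st.SegregationResult | None = None,
    top_n: int = 35,
    candidates: pd.DataFrame | None = None,
) -> str:
    """Human-readable markdown summary of one run."""
    lines = ["# BSA-seq scan summary", ""]
    lines += ["## Variant filtering", ""]
    lines.append(f"- input biallelic SNPs: {n_input}")
    for rule, n in removed.items():
        lines.append(f"- removed by {rule}: {n}")
    lines.append(f"- parent-informative SNPs analysed: {n_informative}")
    lines.append("")
    if segregation is not None:
        lines += [
            "## Phenotype segregation",
            "",
            f"- observed (Green, Purple-green, Purple): {segregation.observed}",
            f"- expected ratio {':'.join(str(int(w)) for w in segregation.expected_ratio)}: "
            f"chi2 = {segregation.chi2:.2f}, df = {segregation.df}, "
            f"P = {segregation.p_value:.2f}",
            "",
        ]
    lines += ["## Thresholds", ""]
    lines.append(f"- ED^4 top-fraction threshold: {result.ed4_threshold:.4g}")
    ci = result.null_ci
    mid = ci.at_depth(min(ci.quantiles), 45)
    lines.append(
        f"- |dSNP-index| 95% null CI at 45x (bulks of {ci.bulk_size}): {float(mid):.3f}"
    )
    lines.append("")
    for name, ivs in (
        ("dSNP-index intervals", result.delta_intervals),
        ("ED^4 intervals", result.ed4_intervals),
        ("Consensus QTL", result.consensus),
    ):
        lines += [f"## {name}", ""]
        if not ivs:
            lines.append("- none (no QTL found)" if "Consensus" in name else "- none")
        for x in ivs:
            lines.append(
                f"- {x.chrom}:{x.start:,}-{x.end:,} "
                f"({iv.interval_width_mb(x):.2f} Mb, {x.n_supporting_snps} supporting SNPs)"
            )
        lines.append("")
    if candidates is not None and not candidates.empty:
        lines += ["## Top candidate SNPs", ""]
        shown = candidates.head(top_n)
        lines.append(shown.to_csv(sep="\t", index=False).rstrip())
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write all artifacts to ``config.out_dir``.

    Returns a dict of the main in-memory results (analysis result,
    filter ledger, summary path).  Every output is reproducible from the
    config plus master seed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    (out / "run_config.json").write_text(json.dumps(_config_payload(config), indent=2))

    truth = None
    segregation = None
    if config.simulate:
        variants_mem, truth = sim.simulate_experiment(
            n=config.sim_n,
            bulk_size=config.sim_bulk_size,
            mean_depth=config.sim_depth,
            error_rate=config.sim_error_rate,
            seed=config.seed,
            qtl_linked=config.sim_qtl_linked,
        )
        vcf_path = out / "simulated.vcf"
        sim.write_vcf(
            variants_mem, vcf_path,
            contig_lengths=sim.GenomeSpec.default().lengths(),
        )
        sim.write_truth_json(truth, out / "truth.json")
        sim.write_phenotypes_csv(truth, out / "phenotypes.csv")
        counts = [int((truth.phenotypes == c).sum()) for c in sim.PHENOTYPE_CLASSES]
        segregation = st.segregation_chi_square(counts, (1, 2, 1))
        config_vcf = str(vcf_path)
        roles = {v: k for k, v in sim.DEFAULT_SAMPLE_NAMES.items()}
    else:
        config_vcf = config.vcf
        roles = config.sample_roles

    variants = vio.read_pooled_vcf(config_vcf, roles)
    n_input = len(variants)
    retained, removed = vio.apply_quality_filters(variants, config.thresholds)
    informative = vio.select_informative_snps(
        retained, config.min_parent_depth, config.max_minor_fraction
    )
    vio.write_variant_table(informative, out / "filtered_variants.tsv")
    vio.write_filter_log(removed, out / "filter_log.tsv")

    if config.phenotypes_csv and segregation is None:
        phen = pd.read_csv(config.phenotypes_csv)
        counts = [
            int((phen["phenotype"] == c).sum()) for c in sim.PHENOTYPE_CLASSES
        ]
        segregation = st.segregation_chi_square(counts, (1, 2, 1))

    result = analyze_variants(
        informative, config.scan_params, config.max_gap, seed=config.seed
    )
    st.write_site_stats(result.sites, out / "site_stats.tsv")
    result.windows.to_csv(out / "windows.tsv", sep="\t", index=False, float_format="%.6g")
    all_ivs = result.delta_intervals + result.ed4_intervals + result.consensus
    iv.intervals_to_frame(all_ivs).to_csv(out / "intervals.tsv", sep="\t", index=False)
    iv.write_bed(result.consensus, out / "consensus.bed")

    candidates = None
    if config.gff3 and config.fasta and result.top_consensus is not None:
        genes = ann.load_gene_models(config.gff3, config.fasta)
        from pyfaidx import Fasta

        genome = Fasta(str(config.fasta))
        in_interval = [
            v for v in informative
            if result.top_consensus.contains(v.chrom, v.pos)
        ]
        effects = ann.annotate_variants(in_interval, genes, genome, config.flank)
        candidates = ann.build_candidate_table(
            effects, result.sites, result.top_consensus
        )
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False,
                          float_format="%.4g")

    if config.make_plots:
        from .plotting import plot_scan

        plot_scan(result, out / "scan_delta.png", statistic="delta")
        plot_scan(result, out / "scan_ed4.png", statistic="ed4")

    summary = summarize_run(
        result, removed, n_input, len(informative), segregation,
        candidates=candidates,
    )
    (out / "summary.md").write_text(summary)
    logger.info("pipeline complete; outputs in %s", out)
    return {
        "result": result,
        "removed": dict(removed),
        "truth": truth,
        "segregation": segregation,
        "candidates": candidates,
        "summary_path": out / "summary.md",
    }
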