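"""Synthetic F2 pooled-sequencing experiments with ground truth.

Emulates the study design the pipeline targets: two inbred parents fixed
for alternate alleles genome-wide, an F2 of n = 646 segregating a single
incompletely dominant locus (Green / Purple-green / Purple at 1:2:1),
extreme bulks of 30 + 30 individuals, and ~45x pooled short-read depth
per sample with a 1% base-error rate folded into the sampled allele
frequency.

Meiosis follows the Haldane (no-interference) model.  At marker
resolution the Poisson crossover process factorises exactly into
independent recombination events between adjacent markers with
probability c = (1 − e^(−2d))/2 for map distance d Morgans, which is how
gametes are sampled here (vectorised over individuals).

The default genome is a 12-chromosome miniature (5 Mb / 50 cM each,
200 SNPs per chromosome) sized so a full simulate-and-scan round trip
runs in well under a second while keeping realistic per-window SNP
counts, linkage decay and read noise.

All randomness flows from one master seed through
``numpy.random.SeedSequence`` spawning, so each stage is reproducible in
isolation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .variant_io import PoolCounts, PooledVariant, SiteQC

PHENOTYPE_CLASSES = ("Green", "Purple-green", "Purple")

#: Default genotype-dosage -> phenotype map for an incompletely dominant
#: locus (dosage counts purple-parent alleles).
DEFAULT_PHENOTYPE_MAP = {0: "Green", 1: "Purple-green", 2: "Purple"}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeSpec:
    """Miniature genome layout: (name, length bp, genetic length cM) per chromosome."""

    chromosomes: tuple[tuple[str, int, float], ...]
    marker_density: float  # SNPs per Mb

    def __post_init__(self) -> None:
        for name, length, cm in self.chromosomes:
            if length <= 0 or cm <= 0:
                raise ValueError(f"chromosome {name}: length and cM must be > 0")
        if self.marker_density <= 0:
            raise ValueError("marker_density must be > 0")

    @classmethod
    def default(cls) -> "GenomeSpec":
        """12 chromosomes x 5 Mb / 50 cM, 40 SNPs/Mb (200 per chromosome)."""
        return cls(
            chromosomes=tuple(
                (f"chr{i + 1:02d}", 5_000_000, 50.0) for i in range(12)
            ),
            marker_density=40.0,
        )

    def lengths(self) -> dict[str, int]:
        return {name: length for name, length, _ in self.chromosomes}


@dataclass(frozen=True)
class QtlSpec:
    """A single causal locus with an incomplete-dominance phenotype map."""

    chrom: str
    pos: int
    dominance: str = "incomplete"
    phenotype_map: Mapping[int, str] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_MAP)
    )
    misclassification_rate: float = 0.0

    def __post_init__(self) -> None:
        if set(self.phenotype_map) != {0, 1, 2}:
            raise ValueError("phenotype_map must cover dosages {0, 1, 2}")
        if not 0 <= self.misclassification_rate < 0.5:
            raise ValueError("misclassification_rate must lie in [0, 0.5)")

    @classmethod
    def default(cls) -> "QtlSpec":
        """Causal locus at the centre of chr05 of the default genome."""
        return cls(chrom="chr05", pos=2_500_000)


@dataclass
class F2Population:
    """Genotype dosages of an F2 population on a marker map.

    ``genotypes[chrom]`` is an (n_individuals, n_markers) array of
    purple-parent allele dosages in {0, 1, 2}; the purple parent carries
    the alternate allele at every marker, the green parent the reference.
    """

    genome: GenomeSpec
    positions: dict[str, np.ndarray]  # bp, sorted, per chromosome
    genotypes: dict[str, np.ndarray]
    qtl: QtlSpec
    qtl_index: int  # index of the causal marker within positions[qtl.chrom]

    @property
    def n(self) -> int:
        return next(iter(self.genotypes.values())).shape[0]

    def qtl_dosages(self) -> np.ndarray:
        return self.genotypes[self.qtl.chrom][:, self.qtl_index]


@dataclass
class SimTruth:
    """Ground truth of one synthetic experiment."""

    qtl: QtlSpec
    qtl_linked: bool  # False for no-QTL (null) experiments
    phenotypes: np.ndarray
    bulk_purple: np.ndarray  # individual indices
    bulk_green: np.ndarray
    positions: dict[str, np.ndarray]
    true_freq_bulk_purple: dict[str, np.ndarray]
    true_freq_bulk_green: dict[str, np.ndarray]
    seed: int


def _marker_positions(genome: GenomeSpec, qtl: QtlSpec, rng: np.random.Generator):
    """Draw sorted unique marker positions; the causal position is a marker."""
    positions: dict[str, np.ndarray] = {}
    qtl_index = -1
    for name, length, _ in genome.chromosomes:
        n_markers = max(2, int(round(genome.marker_density * length / 1e6)))
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n_markers, replace=False))
        if name == qtl.chrom:
            if not 1 <= qtl.pos <= length:
                raise ValueError(f"QTL position {qtl.pos} outside {name} (1..{length})")
            pos = np.unique(np.append(pos, qtl.pos))
            qtl_index = int(np.searchsorted(pos, qtl.pos))
        positions[name] = pos
    if qtl_index < 0:
        raise ValueError(f"QTL chromosome {qtl.chrom!r} not in genome")
    return positions, qtl_index


def _gametes(pos: np.ndarray, length: int, cm: float, n_gametes: int,
             rng: np.random.Generator) -> np.ndarray:
    """Sample F1 gametes at the given markers under the Haldane model.

    Map positions are proportional to physical position (uniform
    recombination rate).  Returns (n_gametes, n_markers) alleles in
    {0, 1}; 1 = purple-parent allele.
    """
    morgans = (pos / length) * (cm / 100.0)
    d = np.diff(morgans)
    c = 0.5 * (1.0 - np.exp(-2.0 * d))  # Haldane map function per interval
    start = rng.integers(0, 2, size=(n_gametes, 1))
    switches = rng.random(size=(n_gametes, d.size)) < c
    state = np.concatenate([start, switches], axis=1)
    return np.cumsum(state, axis=1) % 2


def simulate_f2_population(
    genome: GenomeSpec,
    n: int,
    qtl: QtlSpec,
    seed: int = 0,
) -> F2Population:
    """Simulate F2 genotype dosages from two inbred parents.

    Parents are fixed for opposite alleles at every marker; each F2
    genotype is the sum of two independent F1 gametes per chromosome.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    positions, qtl_index = _marker_positions(genome, qtl, rng)
    genotypes: dict[str, np.ndarray] = {}
    for name, length, cm in genome.chromosomes:
        g1 = _gametes(positions[name], length, cm, n, rng)
        g2 = _gametes(positions[name], length, cm, n, rng)
        genotypes[name] = (g1 + g2).astype(np.int8)
    return F2Population(genome, positions, genotypes, qtl, qtl_index)


def assign_phenotypes(
    dosages: np.ndarray,
    qtl: QtlSpec,
    seed: int = 0,
) -> np.ndarray:
    """Map causal-locus dosages to phenotype classes.

    Dosage 2 -> Purple, 1 -> Purple-green, 0 -> Green (by
    ``qtl.phenotype_map``); with probability ``misclassification_rate`` a
    class is replaced by an adjacent class (the heterozygote flips to a
    uniformly chosen homozygous class).
    """
    rng = np.random.default_rng(seed)
    classes = np.array([qtl.phenotype_map[int(d)] for d in dosages], dtype=object)
    rate = qtl.misclassification_rate
    if rate > 0:
        flip = rng.random(len(classes)) < rate
        for i in np.nonzero(flip)[0]:
            if classes[i] == "Purple-green":
                classes[i] = "Purple" if rng.random() < 0.5 else "Green"
            elif classes[i] == "Purple":
                classes[i] = "Purple-green"
            else:
                classes[i] = "Purple-green"
    return classes


def select_bulks(
    classes: np.ndarray,
    bulk_size: int = 30,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample the extreme bulks: ``bulk_size`` Purple and ``bulk_size`` Green.

    Uniform sampling without replacement within each extreme class;
    raises if either class is smaller than the bulk.
    """
    rng = np.random.default_rng(seed)
    purple = np.nonzero(classes == "Purple")[0]
    green = np.nonzero(classes == "Green")[0]
    if len(purple) < bulk_size or len(green) < bulk_size:
        raise ValueError(
            f"not enough extreme individuals for bulks of {bulk_size}: "
            f"{len(purple)} Purple, {len(green)} Green"
        )
    return (
        np.sort(rng.choice(purple, size=bulk_size, replace=False)),
        np.sort(rng.choice(green, size=bulk_size, replace=False)),
    )


def _sample_reads(freq: np.ndarray, mean_depth: float, error_rate: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Poisson depth, binomial alt reads at error-folded frequency."""
    depth = rng.poisson(mean_depth, size=freq.shape)
    p = freq * (1.0 - error_rate) + (1.0 - freq) * error_rate
    alt = rng.binomial(depth, p)
    return depth, alt


def simulate_pool_reads(
    pop: F2Population,
    bulk_purple: np.ndarray,
    bulk_green: np.ndarray,
    mean_depth: float = 45.0,
    error_rate: float = 0.01,
    seed: int = 0,
) -> tuple[list[PooledVariant], dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Sample pooled read counts for the four samples at every marker.

    Per bulk and marker the true alternate-allele frequency is the mean
    dosage / 2 over bulk members; parents are sequenced from their fixed
    genotypes (purple all-alt, green all-ref).  Site depth is
    Poisson(mean_depth) per sample; alternate reads are binomial at the
    error-folded frequency.  Returns the variant list plus the true bulk
    frequencies per chromosome.
    """
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    rng = np.random.default_rng(seed)
    variants: list[PooledVariant] = []
    truth_p: dict[str, np.ndarray] = {}
    truth_g: dict[str, np.ndarray] = {}
    for name, _, _ in pop.genome.chromosomes:
        pos = pop.positions[name]
        geno = pop.genotypes[name]
        fp = geno[bulk_purple].mean(axis=0) / 2.0
        fg = geno[bulk_green].mean(axis=0) / 2.0
        truth_p[name], truth_g[name] = fp, fg
        freqs = {
            "parent_purple": np.ones_like(fp),
            "parent_green": np.zeros_like(fp),
            "bulk_purple": fp,
            "bulk_green": fg,
        }
        reads = {
            role: _sample_reads(f, mean_depth, error_rate, rng)
            for role, f in freqs.items()
        }
        ref_idx = rng.integers(0, 4, size=pos.size)
        alt_shift = rng.integers(1, 4, size=pos.size)
        refs = _BASES[ref_idx]
        alts = _BASES[(ref_idx + alt_shift) % 4]
        site_dp = sum(depth for depth, _ in reads.values())
        for j in range(pos.size):
            counts = {
                role: PoolCounts(
                    ref_depth=int(depth[j] - alt[j]), alt_depth=int(alt[j])
                )
                for role, (depth, alt) in reads.items()
            }
            qc = SiteQC(
                dp=float(site_dp[j]), qual=999.0, mq=60.0, qd=25.0,
                fs=2.0, an=8.0, sor=1.0,
            )
            variants.append(
                PooledVariant(
                    chrom=name, pos=int(pos[j]), ref=str(refs[j]), alt=str(alts[j]),
                    qc=qc, counts_by_sample=counts,
                )
            )
    return variants, truth_p, truth_g


def simulate_experiment(
    genome: GenomeSpec | None = None,
    qtl: QtlSpec | None = None,
    n: int = 646,
    bulk_size: int = 30,
    mean_depth: float = 45.0,
    error_rate: float = 0.01,
    seed: int = 0,
    qtl_linked: bool = True,
) -> tuple[list[PooledVariant], SimTruth]:
    """Run the full generator: population, phenotypes, bulks, pooled reads.

    With ``qtl_linked=False`` phenotypes are drawn from the 1:2:1 class
    distribution independently of genotype — the no-QTL null experiment
    used for specificity checks.
    """
    genome = genome or GenomeSpec.default()
    qtl = qtl or QtlSpec.default()
    ss = np.random.SeedSequence(seed)
    s_pop, s_phen, s_bulk, s_reads = [int(c.generate_state(1)[0] % 2**31)
                                      for c in ss.spawn(4)]
    pop = simulate_f2_population(genome, n, qtl, seed=s_pop)
    if qtl_linked:
        classes = assign_phenotypes(pop.qtl_dosages(), qtl, seed=s_phen)
    else:
        rng = np.random.default_rng(s_phen)
        classes = rng.choice(
            np.array(PHENOTYPE_CLASSES, dtype=object), size=n, p=[0.25, 0.5, 0.25]
        )
    bulk_purple, bulk_green = select_bulks(classes, bulk_size, seed=s_bulk)
    variants, truth_p, truth_g = simulate_pool_reads(
        pop, bulk_purple, bulk_green, mean_depth, error_rate, seed=s_reads
    )
    truth = SimTruth(
        qtl=qtl,
        qtl_linked=qtl_linked,
        phenotypes=classes,
        bulk_purple=bulk_purple,
        bulk_green=bulk_green,
        positions=pop.positions,
        true_freq_bulk_purple=truth_p,
        true_freq_bulk_green=truth_g,
        seed=seed,
    )
    return variants, truth


# ---------------------------------------------------------------------------
# on-disk emission

DEFAULT_SAMPLE_NAMES = {
    "parent_purple": "EP02_pool",
    "parent_green": "EP01_pool",
    "bulk_purple": "ZS_pool",
    "bulk_green": "LS_pool",
}

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=bsascan-simulate
##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth across samples">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled Fisher strand bias">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Total number of alleles in called genotypes">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio of strand bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def _gt(counts: PoolCounts) -> str:
    if counts.total_depth == 0:
        return "./."
    f = counts.alt_depth / counts.total_depth
    if f < 0.1:
        return "0/0"
    if f > 0.9:
        return "1/1"
    return "0/1"


def write_vcf(
    variants: Sequence[PooledVariant],
    path: str | Path,
    sample_names: Mapping[str, str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write variants as a four-sample VCF v4.2 (GT:AD:DP per sample)."""
    sample_names = dict(sample_names or DEFAULT_SAMPLE_NAMES)
    roles = list(sample_names)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names[r] for r in roles) + "\n"
        )
        for v in variants:
            qc = v.qc

            def fmt(x, spec="{:g}"):
                return "." if x is None else spec.format(x)

            info = (
                f"DP={fmt(qc.dp, '{:.0f}')};MQ={fmt(qc.mq)};QD={fmt(qc.qd)};"
                f"FS={fmt(qc.fs)};AN={fmt(qc.an, '{:.0f}')};SOR={fmt(qc.sor)}"
            )
            samples = []
            for role in roles:
                c = v.counts(role)
                samples.append(f"{_gt(c)}:{c.ref_depth},{c.alt_depth}:{c.total_depth}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{fmt(qc.qual)}\t"
                f"PASS\t{info}\tGT:AD:DP\t" + "\t".join(samples) + "\n"
            )


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    """Serialise the experiment's ground truth (positions, frequencies, bulks)."""
    payload = {
        "seed": truth.seed,
        "qtl": {
            "chrom": truth.qtl.chrom,
            "pos": truth.qtl.pos,
            "dominance": truth.qtl.dominance,
            "misclassification_rate": truth.qtl.misclassification_rate,
            "linked": truth.qtl_linked,
        },
        "bulk_purple": truth.bulk_purple.tolist(),
        "bulk_green": truth.bulk_green.tolist(),
        "phenotype_counts": {
            c: int((truth.phenotypes == c).sum()) for c in PHENOTYPE_CLASSES
        },
        "true_freq_bulk_purple": {
            c: np.round(f, 6).tolist() for c, f in truth.true_freq_bulk_purple.items()
        },
        "true_freq_bulk_green": {
            c: np.round(f, 6).tolist() for c, f in truth.true_freq_bulk_green.items()
        },
        "positions": {c: p.tolist() for c, p in truth.positions.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def write_phenotypes_csv(truth: SimTruth, path: str | Path) -> None:
    """Per-individual phenotype classes and bulk membership as CSV."""
    in_p = set(truth.bulk_purple.tolist())
    in_g = set(truth.bulk_green.tolist())
    with open(path, "w") as fh:
        fh.write("individual,phenotype,bulk\n")
        for i, cls in enumerate(truth.phenotypes):
            bulk = "purple" if i in in_p else ("green" if i in in_g else "")
            fh.write(f"{i},{cls},{bulk}\n")
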