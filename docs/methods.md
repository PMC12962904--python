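# Methods

## Study design and model

The pipeline assumes the classical BSA-seq design: two inbred parental
lines fixed for opposite alleles, an F2 population segregating the trait,
and two DNA bulks pooled from the phenotypic extremes (here 30 + 30
individuals), each sequenced as one pooled library alongside the two
parents. At a marker unlinked to the causal locus both bulks are random
draws from the F2 and their allele frequencies agree in expectation; at a
marker linked to the locus the extreme bulks are enriched for opposite
parental alleles and the frequencies diverge, approaching fixation at the
locus itself. The trait model is a single locus with incomplete dominance:
genotype dosages 0/1/2 map to three distinguishable phenotype classes
segregating 1:2:1, tested by a Pearson χ² goodness-of-fit (df = 2, no
continuity correction).

## Per-site statistics

For each biallelic SNP and each bulk, the SNP-index is the alternate-read
fraction f = alt/(alt+ref). The two association statistics are

* ΔSNP-index = f(green bulk) − f(purple bulk). The subtraction order is
  fixed; the sign of a peak depends on which parent carries the ALT allele
  at the locus, so all thresholding uses |Δ| while reports keep the sign.
* ED⁴, the fourth power of the Euclidean distance between the bulks'
  allele-frequency vectors. For biallelic sites Δf_ref = −Δf_alt exactly,
  so ED = √2·|Δf_alt| and ED⁴ = 4·Δf_alt⁴ ∈ [0, 4]. The code computes ED
  through this identity rather than the two-term square root: the two are
  algebraically identical, but the two-term form loses ~4 significant
  digits to cancellation at small Δ and would break the ED⁴ = 4Δ⁴
  invariant at tight tolerances.

Sites with zero depth in a bulk are undefined (NaN) and excluded from
scans. No pseudocounts are added: upstream depth filters make zero-depth
sites rare, and imputation would distort the fixation identities (Δ = ±1,
ED⁴ = 4) that make the statistics interpretable.

## Site filtering

Hard filters follow GATK-style thresholds for pooled resequencing:
DP ∈ [60, 1000] (site depth summed over the four samples; the bracket is
roughly 4 × 45× per-sample depth ± a generous margin), QUAL ≥ 50, MQ ≥ 50,
QD ≥ 2, FS ≤ 40, AN ≥ 5, SOR ≤ 5. Boundary values pass. A missing metric
fails its rule — the filters select highly reliable variants, so absence
of evidence excludes. Removal counts attribute each record to the first
violated rule in the order above. Multiallelic and non-SNP records are
dropped outright because the ED⁴/Δ identities assume biallelic sites.

Parent-informative sites are those where each parental pool has depth ≥ 10
and minor-allele read fraction ≤ 0.05 (effective homozygosity), with
opposite major alleles. The depth and tolerance are exposed as parameters;
the defaults accept ~1–2 stray reads at 45× while rejecting genuinely
heterozygous or mis-called parental sites.

## Genome scan

Per-site tracks are aggregated into sliding windows of 1 Mb with a 500 kb
step, anchored at position 1 of each chromosome; terminal windows are
truncated, not dropped. Windows with fewer than 10 SNPs carry undefined
means and never contribute to thresholds or intervals. Window means and
the per-SNP ED⁴ track are smoothed per chromosome by LOESS (tricube
weights, local linear fit, via statsmodels `lowess` with no robustness
iterations, so the fit is deterministic). The span defaults to 0.1 of a
chromosome's points, floored at 3 points so every local degree-1 fit is
determined; tracks with fewer than 10 defined points are returned
unsmoothed with a warning.

Two significance rules:

* **ED⁴** — the threshold is the empirical 99th percentile (linear
  interpolation between order statistics) of raw per-SNP ED⁴ values
  genome-wide. Candidate regions are where the LOESS-fitted per-SNP ED⁴
  track exceeds this threshold. The comparison is made at SNP resolution
  deliberately: a 1 Mb window mean dilutes a linkage peak several-fold,
  and a threshold defined on raw per-SNP extreme order statistics can then
  never be reached by any window-level average, whereas the fitted per-SNP
  track tracks the peak height. Windows are flagged when they overlap
  above-threshold fitted SNPs, which lets both methods share the interval
  machinery; the window-level mean and fitted ED⁴ tracks are still emitted.
* **ΔSNP-index** — a simulation null for the pooled design. Per replicate,
  each bulk's true allele frequency is the mean dosage/2 of `bulk_size`
  F2 genotypes (dosage ~ Binomial(2, ½), i.e. 1:2:1), and alt reads are
  Binomial(depth, f); the 95%/99% quantiles of |Δ| are tabulated on a
  depth grid (10…1000×, 10,000 replicates by default) and interpolated at
  each window's mean bulk depth. A window is flagged when its fitted |Δ|
  exceeds the 95% quantile. Comparing a window mean against a per-SNP
  quantile is conservative under the null (averaging shrinks noise), which
  is the safe direction for specificity; the linked-locus signal (|Δ| → 1)
  clears the bound by an order of magnitude regardless.

## Interval calling

Flagged windows are merged into maximal runs, bridging unflagged gaps of
up to one step (500 kb) so a single sparse window cannot split a QTL. Run
boundaries are then snapped to the first and last significant raw SNP
inside the run (ED⁴: raw value ≥ threshold; Δ: |Δ| ≥ the 95% null quantile
at the site's depth) — this is why reported bounds coincide with real SNP
coordinates rather than window edges; runs containing no significant SNP
keep window-edge bounds. Per-method intervals are intersected pairwise
(max of starts, min of ends) into the consensus QTL, and a consensus
interval is only reported if it contains at least one SNP significant
under **both** statistics — making explicit an anchoring property the
two-method design implies, and markedly improving null specificity.
Interval width is reported as (end − start)/10⁶ Mb; the `end − start`
convention (not +1) matches how such bounds are conventionally quoted and
is applied consistently. Coordinates are 1-based inclusive everywhere
except BED exports (0-based half-open).

## Annotation

Gene models come from GFF3 via gffutils; only the longest-CDS transcript
per gene is used. Genes with no CDS, CDS length not divisible by 3, or
exon/CDS containment violations are skipped with a log message. Effect
categories partition every SNP: CDS → EXON:SYNONYMOUS/NON_SYNONYMOUS
(reference codon built strand-aware from the FASTA, ALT substituted —
reverse-complemented on minus-strand genes — both translated with the
standard nuclear code; a VCF-REF/FASTA disagreement is an error naming the
site), exon-not-CDS → UTR_5′/3′ by strand-aware position, otherwise
INTRON; within 5 kb of a gene → UPSTREAM/DOWNSTREAM strand-aware (nearest
gene wins ties); else INTERGENIC. When overlapping genes give several
calls, the candidate table keeps the most severe (non-synonymous >
synonymous > UTR > intron > flanking). The candidate table is restricted
to the consensus interval and sorted by descending |Δ| then descending
ED⁴ (the signed Δ is kept as a column; sorting on |Δ| keeps the ordering
independent of which parent carries ALT).

## Synthetic experiments

The generator emulates the target study design end to end with ground
truth at every stage. Defaults are the study conditions: n = 646 F2
individuals, a single incompletely dominant locus, 30 + 30 extreme bulks,
45× mean pooled depth, 1% sequencing error. The genome is a 12-chromosome
miniature — 5 Mb / 50 cM per chromosome, 200 SNPs each (≈2,400 markers) —
sized so a full simulate-and-scan round trip takes well under a second
while preserving the features the scan depends on: realistic per-window
SNP counts, linkage decay over a few cM around the causal locus, F2
sampling noise in bulks of 30, and binomial read noise at 45×. The causal
position (centre of chr05) is always included as a marker.

Meiosis is the Haldane (no-interference) model. Rather than sampling
Poisson crossover breakpoints, gametes are generated by independent
Bernoulli recombination events between adjacent markers with
c = (1 − e^(−2d))/2 for map distance d — the exact factorisation of the
no-interference crossover process at marker resolution, identical in
distribution to breakpoint sampling at the markers the simulator emits,
and fully vectorisable. Genetic position is proportional to physical
position (uniform recombination rate).

Phenotypes map dosage 0/1/2 → Green/Purple-green/Purple, with an optional
adjacent-class misclassification rate (default 0: the design assumes
phenotype classes verified by repeated observation). Bulks sample
uniformly without replacement from the two homozygous-phenotype classes.
Pooled reads: per sample and marker, depth ~ Poisson(mean depth) and alt
reads ~ Binomial(depth, f·(1−e) + (1−f)·e), folding sequencing error into
the allele frequency — adequate for count-level statistics, since the
pipeline never sees individual reads. Parents are sequenced from their
fixed genotypes. Null (no-QTL) experiments draw phenotypes from the 1:2:1
class distribution independently of genotype. All randomness derives from
one master seed through `SeedSequence` spawning, so any stage is
reproducible in isolation and identical seeds give byte-identical outputs.

What the simulator does *not* model: read alignment artifacts, mapping
bias, variant-calling error beyond the site-QC fields it stamps as
passing, multiallelic sites, structural variation, crossover interference,
and segregation distortion. Passing recovery tests therefore demonstrates
the statistical machinery under clean pooled-count assumptions, not
robustness to alignment- or caller-induced artifacts in real data.

## Verification at scale

The simulation-based properties run at the miniature-genome scale above:
parameter recovery (consensus interval contains the true causal position)
and null specificity (no consensus interval reported) are each evaluated
over 50 seeded experiments, and null calibration of the window CI over 20;
these sizes keep the whole suite fast while leaving Monte-Carlo margins
well clear of the pass bounds.

## Known limitations

* The ΔSNP-index null assumes an F2 design; other cross types
  (RIL, backcross) are rejected rather than approximated.
* Depth-matched CI interpolation uses each window's mean bulk depth; sites
  with strongly heterogeneous depth inside one window are summarised by
  that mean.
* Annotation considers one canonical transcript per gene; multi-isoform
  effect enumeration is out of scope, as are homology search and
  functional enrichment.
* LOESS span is a fixed fraction (no bandwidth auto-selection); on very
  short window tracks the 3-point floor makes smoothing weak by design
  rather than extrapolating an under-determined fit.
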