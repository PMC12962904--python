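# bsascan

Bulked-segregant analysis (BSA-seq) QTL mapping for biparental crosses.

`bsascan` maps a qualitative or near-qualitative trait from four pooled
whole-genome sequencing samples — two inbred parents and two bulks of
extreme-phenotype F2 individuals — the design used to map loci such as the
eggplant young-leaf anthocyanin locus on chromosome 10. It takes a finished
multi-sample VCF (plus optional GFF3/FASTA for annotation) and produces
per-SNP association tracks, genome scans, a consensus QTL interval and a
candidate-SNP table. A built-in simulator generates complete synthetic F2
pooled-sequencing experiments with ground truth, so every stage of the
pipeline is verifiable without external data.

## The statistics

For each biallelic SNP, with alternate-allele read fraction
*f* = alt/(alt+ref) in each bulk (the **SNP-index**):

- **ΔSNP-index** = *f*(green bulk) − *f*(purple bulk). Markers tightly
  linked to the causal locus approach ±1 (the sign depends on which parent
  carries the ALT allele); unlinked markers hover near 0. Significance is a
  simulation-based null: each bulk's true allele frequency is the mean
  genotype dosage of 30 F2 individuals under Mendelian segregation, read
  counts are binomial at the observed depth, and the 95%/99% quantiles of
  |Δ| form the confidence interval.
- **ED⁴** — the Euclidean distance between the two bulks' allele-frequency
  vectors, ED = √(Δf²_alt + Δf²_ref) = √2·|Δf_alt|, raised to the fourth
  power to suppress background noise (maximum 4 at opposite fixation). The
  genome-wide top 1% of per-SNP ED⁴ values is the significance threshold;
  candidate regions are where the LOESS-fitted ED⁴ track exceeds it.

Candidate intervals from the two methods are intersected into a **consensus
QTL**; interval bounds are snapped to significant raw SNP coordinates, and
phenotype class counts can be tested against a Mendelian 1:2:1 ratio by a
Pearson χ² goodness-of-fit.

## Worked example

Simulate a default experiment (F2 of n = 646, one incompletely dominant
locus at chr05:2,500,000 of a 12 × 5 Mb miniature genome, 30+30 extreme
bulks, ~45× pooled depth) and analyse it in one go:

```bash
bsascan run --simulate --out demo --seed 1
```

The run writes the VCF, truth JSON, per-SNP and window tracks, interval
TSV/BED files, scan figures and a summary, ending with:

```
## Phenotype segregation

- observed (Green, Purple-green, Purple): (181, 300, 165)
- expected ratio 1:2:1: chi2 = 4.07, df = 2, P = 0.13

## Thresholds

- ED^4 top-fraction threshold: 3.586
- |dSNP-index| 95% null CI at 45x (bulks of 30): 0.267

## dSNP-index intervals

- chr05:38,059-4,976,653 (4.94 Mb, 198 supporting SNPs)

## ED^4 intervals

- chr05:1,942,669-2,945,906 (1.00 Mb, 22 supporting SNPs)

## Consensus QTL

- chr05:1,942,669-2,945,906 (1.00 Mb, 22 supporting SNPs)
```

The segregation fits 1:2:1 (single incompletely dominant gene); both scans
flag only chr05; and the consensus interval brackets the true causal
position at 2.5 Mb. With a GFF3 and FASTA (`--config` keys `gff3`/`fasta`)
the run also emits `candidates.tsv` — position, ΔSNP-index, ED⁴, REF/ALT,
effect category (EXON:NON_SYNONYMOUS_CODING … INTERGENIC) and gene — for
every SNP in the consensus interval.

Stage-wise subcommands (`simulate`, `filter`, `scan`, `intervals`,
`annotate`) read and write the same on-disk interfaces, and everything is
importable as a library (`bsascan.analyze_variants`,
`bsascan.simulate_experiment`, …).

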