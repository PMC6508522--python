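# Methods

This note records the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical choices that affect results.

## Study design being modeled

Two substantially inbred accessions (SH-like and YK-like roles) are
profiled once each by deep cDNA sequencing during the dark period;
gene-level counts come from uniquely aligned reads. Metabolite
profiles are measured in two independent experiments: experiment 1
covers the two parents with n = 4 replicates, experiment 2 adds the
F1 hybrid with n = 3 replicates per genotype. A qRT-PCR panel
validates candidate differentially expressed genes against an
*Actin2*-role reference gene.

## SNP calling

Candidates are sites where the per-accession consensus bases differ
with depth ≥ `min_depth` (3) in both accessions and mapping quality ≥
`min_mapq` (15). Consensus ties break to the alphabetically first
base; such ties essentially never occur at realistic depth.

Removal filters (annotations, never drops — so the PASS set is
independent of evaluation order):

* `het_within_accession` — an accession's minor allele exceeds
  `monomorphic_max_minor_fraction` (10%) **and** reaches
  `het_min_minor_reads` (3) supporting reads. The read-support floor
  mirrors the 3-read rule used for alternative alleles: one or two
  stray miscalls at moderate depth are sequencing noise, not
  heterozygosity, and without the floor a fraction of genuine SNPs
  would be discarded whenever two same-base miscalls land at depth
  below ~20.
* `not_biallelic` — more than two alleles among {reference,
  alternative, consensus₁, consensus₂}.
* `low_alt_reads` — fewer than `min_alt_reads` (3) alternative reads
  pooled over both accessions.
* `low_alt_fraction` — alternative allele below `min_alt_fraction`
  (10%) of aligned reads. Pooling across both accessions is the
  default reading of "aligned reads"; a per-accession variant is
  available via `alt_fraction_mode`.
* `ref_discordant` — accession-1 consensus differs from the reference
  base (the reference genome is the accession-1 line).
* `snp_cluster` — the call lies in some 100-bp window
  (`cluster_window_bp`) holding **more than** `cluster_max_snps` (4)
  PASS candidates. The strict inequality follows the rule's primary
  statement ("more than four"); the threshold is configurable because
  the rule is also paraphrased elsewhere as "four within 100 bp". The
  two-pointer sweep equals the exhaustive all-windows evaluation
  because every maximal window is anchored at a leftmost candidate
  (property-tested against brute force).

Site quality is 10/ln 10 times the log-likelihood ratio of
"two fixed, distinct alleles" versus the best "one shared allele"
model with a symmetric per-read error rate of 10⁻³, capped at 999.
Only the cap behavior is load-bearing: calls at 999 form the
high-quality tier. This is deliberately not a reimplementation of any
particular genotype-likelihood engine.

## Replicate-free differential expression

Size factors are median-of-ratios: the column factor is the median
over all-positive genes of the count's ratio to the per-gene geometric
mean. Scaling a column rescales its factor proportionally and shifts
normalized counts only by a global constant, leaving every
between-column comparison unchanged.

Dispersions are estimated blind (both columns pooled as one
condition) by method of moments, then a parametric trend
α(μ) = a₀ + a₁/μ is fit by gamma-family IRLS over genes with positive
raw dispersion. If the fit diverges (negative coefficients,
singularity, or non-convergence) a Gaussian-kernel regression of log α
on log μ takes over. Only the fitted value is used per gene
("fit-only" sharing) with a floor of 10⁻⁸. Fit-only sharing is the
conservative choice for n = 1 + 1: genuine expression differences
inflate blind dispersions, so only large folds reach significance —
the intended behavior of the original analysis contract, which found
31 DEGs among ~18k genes at FDR 0.2.

The per-gene test is the exact conditional NB test described in the
README. A split (a, S−a) counts toward the p-value when its joint
probability is ≤ the observed split's probability times (1 + 10⁻⁸);
the tolerance keeps mathematically tied splits (e.g. the mirror split
under equal size factors) inside the rejection sum so that identical
columns give exactly p = 1. BH adjustment is a literal step-up
implementation, verified against an independent oracle.

Fold display uses one decimal, rounding half away from zero, matching
printed convention; full precision is retained internally. Raw-count
folds are the primary report because the published table's folds are
exactly reproduced by raw (not normalized) ratios.

## qPCR

Technical replicates are averaged per dilution point before the CT ~
log₁₀(concentration) regression, so a single outlier well cannot
dominate the slope. The efficiency pass band [0.80, 1.10] is inclusive
at both ends. "No amplification" is a missing CT (empty field), never
CT = 0; the reader rejects CT = 0 outright.

## Metabolite statistics

* Parent contrasts: two-sample two-tailed t tests, pooled variance by
  default (classical usage at n = 3–4), Welch behind a flag.
* Tukey's studentized range over the three genotypes of experiment 2,
  via the standard studentized-range distribution. With a zero
  mean-square error the comparison is degenerate: equal means report
  p = 1, unequal means p = 0.
* The combined analysis is an additive two-factor fixed-effects ANOVA
  (experiment + genotype, no interaction), implemented as nested
  least-squares fits with type-II F tests so unbalanced layouts
  (n = 4 vs n = 3) are handled exactly; a genotype-within-experiment
  nested coding is available behind a flag. The additive model is the
  primary implementation because the combined analysis is explicitly
  described as two main factors without interaction.
* Mid-parent test: one-sample t of the F1 replicates against the
  constant mid-parent mean with df = n_F1 − 1, using the F1 variance
  only. The mid-parent value comes from the parental means of the
  F1-bearing experiment.
* Transgression: two-sample t of F1 against the extreme parent; the
  label applies only when the F1 mean lies beyond that parent and
  p ≤ .05. Metabolites undetected in one parent are reported
  separately (`parent_detected = "one"`) and excluded from the
  direction binomial.
* No multiple-testing correction across metabolites (matching the
  star-annotation convention); a BH column is emitted as supplementary
  output. Zero-variance contrasts with unequal means are flagged
  untestable rather than given p = 0.

### Heterosis mode classification

Metabolites are assigned additive / dominant / transgressive modes
for recovery benchmarking. Transgression uses the significance rule
above. Among the rest, additive vs dominant is decided by proximity:
the F1 mean is compared with its distance to the mid-parent value
versus the nearer parent mean. A significance-based dominance call
(mid-parent t at n = 3, df = 2) has only ~0.6 power at realistic
effect sizes, so a classifier built on it cannot separate the modes
under the study's own replicate counts; the proximity rule splits the
hypotheses at the quarter-span boundary and is the package's design
choice.

## Category enrichment

The exact two-sided signed-rank p doubles the smaller tail of the
null distribution of W⁺, built by dynamic-programming convolution
over doubled midranks (equivalent to enumerating all 2ⁿ sign
assignments, including tied magnitudes), used for n ≤ 25 nonzero
folds. Above that, a normal approximation with continuity correction
and the standard tie-correction term takes over; the two modes agree
within 0.01 at the crossover. Zero folds are dropped before ranking;
ties take midranks. Items with absence labels or non-finite folds are
excluded. The alternative rank-sum mode (members vs non-members,
Mann–Whitney U) reflects the historical behavior of bin-enrichment
software and sits behind a flag.

## Synthetic-data generator

The generator's defaults are the study conditions:

| parameter | default | basis |
| --- | --- | --- |
| `snp_rate` | 10⁻⁴/bp | ~1 SNP per 10 kb of transcribed sequence |
| `depth_mean` | 20 | per-site depth unspecified upstream; a 4×-coverage-era default, configurable |
| `error_rate` | 0.005 | mid-range substitution miscall rate for pyrosequencing-era reads (0.5–1%) |
| `pav_fraction` | 0.185 | fraction of detected genes expressed in one accession |
| `de_fraction` | 31/17888 | DEG incidence |
| `mean_expression` | 62 reads | >1 M aligned reads over ~18k genes |
| `min_expression` | 5 reads | the table holds *detected* genes; below this, genes would not be rows at all |
| `dispersion` | 0.05 | typical technical NB overdispersion for count data without biological replication |
| `metab_n1`, `metab_n2` | 4, 3 | replicate counts of the two profiling experiments |
| `n_metabolites` | 144 | panel size of the F1-bearing experiment |
| `heterosis_mix` | (0.58, 0.25, 0.03, 0.14) | chosen to echo ~56% of metabolites below mid-parent and ~17% transgressive with a ~5:1 negative skew |
| `transgressive_margin` | 0.5 | transgressive F1 means sit 50% beyond the extreme parent |
| `parental_ratio_range` | (2, 4) | parental fold differences of significant metabolites are typically 2–7× |
| `cv_metab` | 0.1 | replicate CV of internal-standard-normalized GC-MS peak areas |
| `exp_shift_sigma` | 0.3 | unquantified between-experiment environmental shift, lognormal per metabolite |
| `qpcr_slope` | −3.3219 | perfect doubling per cycle |
| `qpcr_sd` | 0.2 | CT replicate noise |

A single integer seed feeds one independent generator stream per
output (pileups, counts, metabolome, qPCR), so any file can be
regenerated alone, bit-identically.

Planted pileup artifacts are disjoint by site: heterozygous
(accession-2 carries a 55–70%/30–45% two-allele mix), low-fraction
(two alternative reads plus one reference read in accession 2 under a
deep, 3×-mean-depth accession-1 site, so the pooled alternative
fraction stays below threshold even when a stray accession-1 miscall
hits the same base), reference-discordant (accession-1 consensus set
to a non-reference allele), and cluster (five clean-looking SNPs
inside one 100-bp window). The ground-truth object records every
planted feature exactly once, so downstream recall/precision need no
access to generator internals.

What the generator does **not** emulate: read-level sequences and
alignment (no FASTQ, no mapping ambiguity), indels, isoform structure,
position-dependent error profiles, GC bias, batch structure beyond the
single experiment-level shift, metabolite identification ambiguity,
and cross-contamination. Passing benchmarks therefore demonstrate
correctness of the statistics and filters under the assumed model,
not robustness to alignment artifacts or chemistry-specific biases in
real data.

## Benchmark problem sizes

The validation suite and the reproduction script size their
simulations for a desk-scale run: SNP-cascade benchmarking uses 1,000
genes (~1 Mbp of pileup, ~100 planted SNPs and ~550 artifacts);
planted-DEG recovery uses 50 libraries of 800 genes with 16 planted
16-fold genes at baseline mean 1,000; type-I calibration uses 10,000
null replicates per test (binomial standard error ≈ 0.22 points at
the 5% level); heterosis-mode confusion aggregates six default-size
metabolomes (~840 scored metabolites). These sizes keep every
benchmark's sampling error well inside its acceptance margin.

## Known limitations

* The exact NB test loops over all splits of a gene's count sum, so
  extremely deep single genes (sums ≫ 10⁶) would be slow; the study's
  depth regime is far below that.
* The dispersion trend is fit on as few as two pseudo-replicates per
  gene; with one library per condition this is the only available
  estimator, and calls at FDR 0.2 should be treated as candidates for
  orthogonal validation (the qPCR stage exists for exactly that).
* The cluster filter flags by candidate position only; it does not
  model the underlying indel that motivates the rule.
* Tukey comparisons and the additive ANOVA assume homoscedastic
  normal errors; metabolite data are used on the measured scale, not
  log-transformed, matching the upstream analysis convention.
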