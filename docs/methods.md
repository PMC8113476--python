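# Methods

## Windowed methylome representation

MeDIP-seq measures methylation as fragment-scale enrichment, summarised
here as non-negative RPM-like scores in fixed 500 bp windows tiled every
250 bp from position 0 of each chromosome. Partial terminal windows are
dropped rather than truncated: a constant window length is required for
CpG densities to be comparable, which the enrichment permutation depends
on. CpG density is expressed so that both bases of each CpG count —
`100 * 2 * count / length` — making 45 CpGs in a 500 bp window 18 %
density; CpGs are counted as forward-strand "CG" occurrences, which is
complete because the dinucleotide is strand-symmetric.

Quantile normalisation maps every sample column onto the across-sample
mean of order statistics, rank for rank. Ties take the mean of the
reference values they span (the standard convention; the choice only
matters for heavily discretised scores). The operation is exactly
idempotent on tie-free data; tie-averaging perturbs the reference by a
vanishing amount on re-application.

All genomic arithmetic is BED-convention (0-based, half-open); overlap
means at least one shared base pair, and strand is ignored — tRNA loci are
treated positionally throughout. tRNA clustering is single-linkage: sorted
genes join a group while the gap to the group's right edge is at most
5 Mb (bedtools `merge -d` semantics), and groups must hold ≥ 5 genes at
≥ 5 genes/Mb of merged span (min start to max end). The span definition
for the density denominator was an open choice; merged-interval span is
the natural one for a merge-based grouping.

## Age models

The cross-sectional models regress each window's quantile-normalised score
on age with four covariate sets: none; batch; the four blood cell counts;
batch plus cell counts. Batch enters as a one-hot categorical with the
first level as reference; cell counts enter as given, without a
compositional transform. The reported p-value is the partial F-test for
the age–methylation term, computed by residualising both age and
methylation on the covariates (Frisch–Waugh–Lovell) — algebraically
identical to full OLS but vectorisable across ~16k windows at once, and
verified against statsmodels to 10 significant digits in the tests. Both
regression orientations are supported: `meth_response`
(methylation ~ age + covariates; slope in score units per year, the
default) and `age_response` (age ~ methylation + covariates). The partial
F p-value is identical either way; only the slope's units change.

Degenerate windows (zero residual score variance, detected at a relative
1e-20 tolerance) return slope 0 and p = 1 with a `zero_variance` flag
rather than being dropped, keeping outputs aligned to inputs. Perfect fits
are clipped to the smallest positive p rather than 0. Rank-deficient
designs raise an error naming the collinear columns.

The longitudinal model keeps participants with ≥ 2 samples spanning ≥ 5
years and adds participant identity as a fixed effect, so the age slope is
identified from within-person change. The twin mixed model regresses age
on batch and cell counts with a random intercept per family plus an extra
variance component shared within monozygotic families — the closest
identifiable rendering of "family and zygosity random effects" in a
variance-components framework — and tests the added methylation term by a
maximum-likelihood chi-square(1) LRT. Because null and alternative share
the random structure, the test is insensitive to this rendering; a
singular fit falls back to the fixed-effects partial F with a logged
warning.

tRNA-level summaries use the any-overlap rule: a tRNA is significant if
any overlapping window passes the threshold; the best window is the
minimum-p one, ties broken by larger |slope| then window name. One window
can overlap two neighbouring tRNAs, and then calls both — a documented
property of the rule, not a bug. Bonferroni thresholds are always computed
as alpha/m from user-supplied m, never transcribed.

## Enrichment

The Fisher test is the one-sided hypergeometric tail on the
significant-by-membership 2×2 table. The permutation test stratifies all
windows by exact CpG count below 45 CpGs (18 %) and pools everything at or
above it: above that density CpG islands are consistently hypomethylated
and counts are too sparse to sample without replacement, so windows there
are treated as exchangeable. Exact-count matching below the threshold is
the tightest reading of "equivalent CpG density distribution" (count and
density are bijective at fixed window length). Each permutation samples
without replacement; draws are independent across permutations. Feature
windows are excluded from the background pool so the empirical null does
not contain the signal. r counts permutations with matched-set counts
**greater than or equal to** the observed count — ties count against the
feature set, the conservative convention — and the empirical p-value
(r+1)/(N+1) can never be 0. Hyper- and hypomethylation can be tested
separately by direction-restricting the significance flags; the headline
test uses hypermethylated-significant windows.

## Synthetic data generator

`simulate_study` emulates a blood MeDIP-seq ageing cohort at desk scale:

- **Genome**: 2 chromosomes × 2 Mb (~16k windows of 500/250 bp) carrying
  100 non-overlapping tRNA genes of 60–86 bp placed ≥ 1 kb apart.
- **CpG counts**: background windows are a mixture of a CpG-poor component
  (negative binomial, mean 4) and a 10 % CpG-rich island/shore component
  (mean 30) spanning intermediate-to-CGI densities; tRNA-overlapping
  windows draw from a denser distribution (mean 25). The rich component
  guarantees the density-matched sampler has candidates in every stratum
  the tRNA windows occupy, and makes density matching consequential.
- **Cohort**: 300 samples by default, ages uniform on 16–82 years
  (the discovery cohort's range), ~93 % female, 2 batches, four blood cell
  counts on a 10⁹ cells/L scale, 30 % of participants in MZ/DZ twin pairs
  sharing family effects (MZ weight 1, DZ weight 0.5), and an optional
  longitudinal fraction revisited 5–16.1 years later.
- **Scores**: baseline(density) + planted age slope at affected tRNA
  windows + batch offset + cell-count effects + participant/family effect
  + Gaussian noise (sd 1), floored at 0. Baseline rises with CpG count as
  a saturating curve (max 8, half-saturation 8 CpGs) and drops to a
  hypomethylated level (1.0) for windows at ≥ 45 CpGs, echoing CGI
  hypomethylation. The default planted effect is 0.02 score-units/yr at
  10 % of tRNAs — roughly the fraction of the real feature set called
  study-wide significant. Noise is Gaussian on the score scale rather
  than a read-count model: the pipeline consumes post-RPM normalised
  scores, so their generative detail is immaterial to the statistics
  under test. Setting `celltype_age_assoc` > 0 plants a myeloid skew
  (neutrophils rise, lymphocytes fall with age), reproducing cell-type
  confounding for model comparisons.

`simulate_pooled_bis` emulates the pooled targeted-bisulfite design: 8
pools (2 per age point at ~4, ~28, ~63, ~78 years; 190 contributors).
Per CpG and pool, depth is lognormal with median 679 reads and log-sd 2.0
— amplicon depth is strongly right-skewed, with the mean several-fold
above the median — and methylated reads are binomial with
p = baseline (2 %) + 5×10⁻⁴/yr × pool age at affected loci, i.e. a ~3.7 %
gain from the 4-year to the 78-year pools, the magnitude seen at
individual hypermethylating tRNAs. Parameter-recovery tests that specify
"depth ≈ 700×" use a near-constant depth law (log-sd 0.05), since that is
the condition they state; the skewed default models the real experiment.

What the generator does **not** emulate: read-level artefacts (mappability,
duplicate fragments, immunoprecipitation efficiency), spatial correlation
of methylation along the genome beyond shared window membership,
non-linear age trajectories (the early-life logarithmic phase of clock
CpGs), and array probe chemistry. Passing tests therefore demonstrate the
correctness and calibration of the statistics under the stated generative
assumptions, not robustness to those real-data complications.

## Targeted bisulfite statistics

Pools — not individuals — are the replicates, so the region-level
"paired t-test" pairs CpG sites across the two age groups, with pools
averaged within group first; the alternative reading (pairing the two
pools per age point) gives only two pairs and is underpowered, so it is
exposed instead through the per-CpG two-sample tests, which are combined
by Fisher's method (and optionally a Brown-type adjustment whose scaled
chi-square moments come from the empirical between-CpG correlations).
Both p-values are reported and labelled. Delta is the plain mean over CpGs
of (older − younger) group methylation. Degenerate cases are explicit:
identical profiles give p = 1; a constant non-zero shift has zero paired
variance and is reported at the p → 0 limit with a `zero_variance` flag;
single-CpG regions return the unpaired per-CpG test with a `single_cpg`
flag. Technical replicates are summed within pool before proportions are
taken. Zero p-values entering Fisher's combination are clipped to 1e-300
so the chi-square tail stays representable.

Rank-sum comparisons report the Mann–Whitney U of the first sample (the
convention R prints as W), exact p-values for ≤ 25 observations without
ties and a tie-corrected normal approximation otherwise, the
Hodges–Lehmann median of pairwise differences, and a one-sided confidence
bound obtained by inverting the test with a normal quantile on the ordered
pairwise differences.

## Problem sizes and determinism

Default problem sizes (16k windows × 300 samples; 1000 permutations;
100–200 simulation replicates in the recovery tests) were chosen so every
analysis and the full test suite run in minutes on one core while leaving
all statistical conclusions at comfortable margins. All generators and
permutations are pure functions of their seed; the CLI derives per-stage
seeds from one master seed by hashing and records them, with output
checksums, in per-stage JSON manifests.

## Known limitations

- The permutation's exact-count matching requires the background to
  contain at least as many windows as the feature set in every stratum;
  tiny genomes can exhaust a stratum, which raises an informative error
  rather than silently relaxing the match.
- The mixed model approximates twin covariance with
  family-plus-MZ-component intercepts; it does not fit a full ACE
  decomposition.
- The Brown adjustment uses the classic polynomial covariance
  approximation, adequate for the handful of CpGs per region but not
  validated for large, strongly dependent batteries of tests.
- Quantile normalisation slightly attenuates planted slopes (it constrains
  every sample to one shared distribution); recovery tests that check
  unbiasedness therefore fit the raw simulated scores.
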