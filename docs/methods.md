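# Methods

This note documents the statistical models behind `oltrecur`, the defaults
of the synthetic cohort generator and what they emulate, the numerical
choices, and the known limitations. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Study design being emulated

A retrospective transplant cohort: 21 hepatocellular-carcinoma patients
within transplant criteria, of whom 9 recur within a 24-month follow-up
window. Every patient contributes a primary tumor (P_T) and adjacent normal
tissue (P_NAT) with RNA counts; 4 of the recurrent patients additionally
contribute the recurrent tumor (R_T), donor-liver adjacent normal (R_NAT)
and recipient blood (P_B) with exome-style variant and coverage data. The
recurrence label is part of the design — it is defined by the observed
24-month outcome — so the cohort generator fixes 9 events among 21
patients: recurrent patients receive event times drawn from the
proportional-hazards model conditional on falling inside the window
(inverse-CDF sampling of the truncated exponential), tumor-free patients
are censored at the horizon. The unconditional two-group exponential model
(`simulate_clinical_survival`) is kept as a separate operation for
calibration and coverage studies, where conditioning would bias type-I
error and CI coverage assessments.

## Generator model

**Germlines.** A panel of SNP loci with minor-allele frequencies uniform on
(0.1, 0.5); recipient and donor genotypes drawn independently per locus
from Hardy–Weinberg proportions. The HWE property is verified per locus
with a 1-df chi-square oracle in the tests.

**Somatic variants.** Each variant belongs to one clone with cancer-cell
fraction `cf`; clones may be nested, so fractions are each bounded by 1 but
need not sum to 1. Expected primary-tumor VAF under the copy-neutral
heterozygous model is `π_PT · cf / 2`. Inside the planted hemizygous
deletion the mutated allele sits on the retained haplotype with probability
1/2; the expected VAF becomes `π · cf · m / (2 − π)` with `m ∈ {0, 1}` and
the local depth scales by `(2 − π)/2`. Depth is Poisson per site, alt reads
binomial, and the symmetric sequencing error ε enters as
`f' = ε + f(1 − 2ε)`. Substitution classes are drawn with a C>T-dominant,
T>G-poorest spectrum and reported on either strand with probability 1/2;
effect classes are weighted so the expected nonsilent/silent ratio is 2.8.
Frameshift-class variants are emitted as 1-bp insertions (a type flag; no
realignment artifacts are modelled).

**Recurrent mixture.** The R_T biopsy consists of a fraction α donor normal
cells, `(1−α)(1−π_RT)` recipient normal cells and `(1−α)π_RT` recipient
tumor cells carrying the retained primary clones (the largest
`round(shared_clone_fraction · n_clones)` clones) plus new private clones.
Germline-SNP alt fractions have expectation `((1−α) g_R + α g_D)/2`; shared
clonal somatic VAFs are diluted by `(1−α)`.

**Coverage.** Per-bin depth is Poisson with mean
`depth_mean × (local copies)/2`, where tumor bins inside the planted region
have `2 − π` copies (`π = π_PT` for P_T, `(1−α)π_RT` for R_T).

**Expression.** Counts are negative binomial with log-normal gene base
means, uniform library-size factors and constant dispersion φ
(`variance = μ + φμ²`; φ = 0 degenerates to Poisson). The planted gene's
P_T mean is multiplied by `2^planted_gene_log2fc` in recurrent patients
only.

## Generator defaults and why

| parameter | default | rationale |
|---|---|---|
| n_patients / n_recurrent / n_sequenced | 21 / 9 / 4 | the cohort structure under study |
| alpha (per sequenced patient) | 0.80, 0.06, 0.55, 0.00 | spans heavy/light/intermediate/absent contamination, the regimes the estimators must resolve |
| purity_pt, purity_rt | 0.8 | typical pathology-assessed HCC purity |
| clone_fractions / shared_clone_fraction / private | (0.9, 0.1) / 0.5 / (0.1) | one clonal + one subclonal population; the clonal one persists at recurrence; one new private clone |
| panel_size / maf_range | 2000 / (0.1, 0.5) | a common-SNP identity/chimerism panel |
| depth_mean | 300 | deep tumor exome; chosen by power analysis so the planted deletion remains segmentable in the most contaminated planted biopsy (expected first-split t ≈ 5.6 at α = 0.55 vs 2.5 at depth 100, against the p < 0.001 split criterion) |
| seq_error ε | 1e-3 | post-filter base error of modern short-read callers; not taken from any publication |
| n_genes / base_mean / φ | 200 / 300 / 0.1 | desk-scale transcriptome with realistic per-gene dispersion |
| planted_gene_log2fc | −1.5 | a 2.8-fold suppression, clearly past the 2-fold screen threshold |
| planted_region / planted_in_k | chr4:40–70 Mb / 3 of 4 | one shared hemizygous deletion recurrent in 3 of 4 sequenced patients |
| hazard_ratio / censor_time / h₀ | 7 / 24 months / 0.02 per month | strong prognostic effect at the cohort's follow-up horizon |

The deletion is planted in the three *least contaminated* sequenced
biopsies: under heavy contamination (α = 0.8) the recurrent-tumor log-ratio
shift is ≈ −0.12 and no segmentation method operating at these depths can
see it, so planting there would make the ground truth unrecoverable by
construction; the heavily contaminated biopsy instead exercises the
contamination estimators.

## Estimators and tests

**Identity check.** Fraction of co-covered loci (depth ≥ 20 in both panels)
with equal genotype dosage; same-individual iff ≥ 0.95. Requires ≥ 50 loci.

**Somatic calling.** Tumor VAF ≥ 0.05, tumor alt reads ≥ 4, matched-normal
(blood) VAF ≤ 0.01, both depths ≥ 20; optional secondary exclusion of
variants present in the adjacent normal above VAF 0.05. All thresholds are
parameters. Donor-difference masking then removes any recurrent-tumor call
at a locus where the R_NAT genotype differs from the P_B genotype; loci
covered by neither panel are kept with a warning flag (the conservative
choice — masking must never add variants, and uncovered loci carry no
evidence of a donor difference).

**Clonal relationship.** Jaccard index over somatic keys with a Poisson
chance-sharing null (`E = |P||R|/callable`, upper-tail p). Origin called
"recipient" iff `p ≤ 1e-6` and `CR ≥ 0.05`. The statistic is symmetric, and
monotone in shared/unique additions.

**Germline contamination MLE.** Informative loci: recipient ≠ donor
genotype, R_T depth ≥ 20, outside copy-number-aberrant R_T segments (the
mixture model assumes two copies per cell; in the pipeline, segments with
|mean log2 ratio| > 0.1 are excluded). Binomial log-likelihood maximized on
an α-grid of step 0.001 with bounded local refinement; exact-boundary
candidates (0 and 1) are compared explicitly so a boundary maximum is
returned exactly. The 95 % CI is the profile-likelihood set
`{α : logL ≥ logL_max − 1.92}` with linear interpolation at the edges.

**Somatic contamination estimator.** Clonal shared variants
(`VAF_PT ≥ 0.8 · π_PT/2`, copy-neutral loci, ≥ 10 required);
`α̂ = clamp(1 − median(VAF_RT/VAF_PT), 0, 1)` under the equal-purity
assumption; seeded percentile bootstrap (1000 resamples) for the CI. The
combined report is the min–max envelope of the available point estimates,
collapsing to a point when only one method succeeds.

**CNV.** Log2 ratios are computed after scaling both depth vectors to a
common library size (the mean of the totals) with a 0.5 pseudocount on that
count scale — the pseudocount must live on the count scale, not on the
fraction scale, or it would swamp the ratio. Recursive binary segmentation
accepts the split maximizing the pooled two-sample t statistic when its
p-value (t, n−2 df) is below 0.001 and both sides keep ≥ 5 bins; it is
deterministic and oracle-checkable by exhaustive split search at small
sizes. State calling assigns the nearest of five purity-parameterized
means, ties toward neutral, with the homo-del mean floored at
`log2(0.05)`. Under this rule a fixed negative log-ratio legitimately deepens
from hemi- to homo-deletion as the assumed purity *decreases* (the same
shift implies a larger underlying loss in an impurer biopsy); the converse
direction is monotone and is what the tests assert. For recurrent tumors
the pipeline calls states at effective purity `(1 − α̂) · π_RT`, using the
germline-MLE α̂ — the contamination estimate feeds back into the CNV arm.
Cross-patient regions: per bin and patient a category from the (P_T, R_T)
state pair (shared/unique × amp/del); bins with ≥ k of n patient votes
merge into regions. GC/mappability correction is omitted (the synthetic
data carries no GC bias); this is a real-data limitation.

**Expression.** Median-of-ratios size factors (median taken on the ratio
scale). Note two exact properties of the in-matrix reference: the statistic
carries a small positive bias of order φ/2 under NB noise (vanishing in the
Poisson limit), and scaling one of m libraries by k scales its factor by
`k^((m−1)/m)` and the others by `k^(−1/m)` — factor ratios scale by k and
fold changes are invariant up to the pseudocount. The NB exact test
conditions on the pair total: all splits of `k_A + k_B` are enumerated
under the two NB marginals (common mean from the average normalized count,
dispersion from the trend), and the p-value is the renormalized probability
of splits no more likely than the observed one; zero totals give p = 1.
Dispersion for the no-replicate pair test is borrowed from a
method-of-moments trend `φ(μ) = a₀ + a₁/μ` fitted on a pseudo-replicate
group (the pooled normal samples), floored at 1e-8. The cohort contrast is
a Welch t-test on per-patient log2 folds (Mann–Whitney available), passing
at `|Δ| ≥ 1` log2 units and raw `p < 0.01` with no multiplicity adjustment
— the screen is deliberately permissive, feeding a downstream intersection
rather than a final call.

**Survival.** Median dichotomization assigns the median value itself to the
low group, so 21 distinct values split 11/10. The reference rule cuts at
`mean(reference) − 2 SD` (sample SD). KM is the product-limit estimator
with median survival the smallest time where S(t) ≤ 0.5. The log-rank test
accumulates observed-minus-expected events with hypergeometric variance
(single-subject risk sets contribute none). Cox regression maximizes the
Efron-tied partial likelihood by Newton–Raphson (covariates centered,
step-halving, |ΔlogL| < 1e-8, ≤ 50 iterations); Wald CIs and p-values per
covariate plus an LRT against the null model. Monotone likelihood
(separation) is detected when a coefficient drifts past 12 in absolute
value and is *flagged, not suppressed* — with 9 events all in one group of
21 patients, an unbounded hazard ratio is the expected output and the flag
is the correct report. The region screen dichotomizes each gene by the
reference rule, fits the multivariate Cox model, ranks by grouping-
coefficient p, and flags genes whose minority group holds < 5 % of
patients; degenerate (single-group) cuts are reported but not fitted.

Covariate encodings for cohort-style tables: HBV binary (or three-level
ordinal where a carrier-status distinction exists), tumor grade ordinal
with range entries at midpoints (I–II → 1.5), age binarized at a
configurable cut (49 by default for the 21-patient design), gender binary.
Either the pre- or post-transplant HBV column may be selected; the packaged
fixture carries both. Non-recurrent patients in cohort fixtures are
censored at the 24-month follow-up horizon, since the design records no
individual censoring times.

## What passing tests do and do not show

The generator's data are idealized: no GC or mappability bias in coverage,
no realignment artifacts around indels, germline panel loci simulated
copy-neutral even inside the planted deletion (the MLE's copy-number
exclusion rule is still exercised against the segments the CNV module
calls), flat clone structure rather than a phylogeny, and independent
genes in the counts matrix. Passing the suite therefore demonstrates
correctness of the estimators under their stated models and recoverability
of planted truth at realistic depths and effect sizes — not robustness to
real-data artifacts the generator does not emulate.

Problem sizes in the routine suite are desk-scale choices: a 4 × 100 Mb
genome in 1 Mb bins, 2000-SNP panels, 200-gene count matrices, 20-seed
repetition for planted-truth recovery, 500-replicate calibration runs.

## Numerical details

- All randomness flows from a single integer seed through named
  `SeedSequence` spawns; identical configurations produce byte-identical
  output files.
- Binomial log-likelihoods use `xlogy` so zero-probability terms at exact
  boundaries are handled without special-casing.
- The NB exact test compares log-probabilities with a 1e-10 slack so the
  observed split is always included in its own tail (p = 1 at the modal
  symmetric split).
- Variant identity is the `(chrom, pos, ref, alt)` tuple; coordinates are
  1-based in variant tables and VCF, 0-based half-open in BED, coverage
  bins and region arithmetic.
- Cox and bootstrap seeds are explicit arguments; the profile-likelihood CI
  uses the 1.92 = χ²₁(0.95)/2 cutoff.
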