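# oltrecur

Integrated genomic analysis of matched primary and post-transplant
recurrent liver tumors.

## The problem

After orthotopic liver transplantation (OLT) for hepatocellular carcinoma,
20–40 % of patients develop recurrent tumors. A recurrent-tumor biopsy is a
cell mixture: recipient-derived tumor cells growing inside (or seeded from)
a donor organ, plus donor-derived normal liver. Analyzing such biopsies
jointly with the matched primary tumor, adjacent normal tissues and
recipient blood raises questions this package answers for computational
biologists working with matched-specimen cohorts:

1. **Tumor origin** — does the recurrent tumor share a clonal origin with
   the primary? A clonal-relationship statistic `CR = |P ∩ R| / |P ∪ R|`
   over the two somatic variant sets, with a Poisson null for chance
   sharing (`E = |P||R| / callable bases`, `p = P(X ≥ |P ∩ R|)`), calls the
   origin.
2. **Donor contamination** — what fraction α of the biopsy is donor tissue?
   Two independent estimators: a binomial maximum likelihood over germline
   SNPs where recipient and donor genotypes differ, with allele-fraction
   model `f_i(α) = ((1−α)·g_R,i + α·g_D,i)/2` folded through the sequencing
   error rate, profile-likelihood 95 % CI; and the dilution of shared clonal
   somatic variant allele fractions, `α = 1 − median(VAF_RT / VAF_PT)`, with
   a bootstrap CI.
3. **Somatic landscape** — tumor/normal somatic calling with
   donor-difference masking (any call where the donor germline differs from
   the recipient germline is removed), shared/unique partitioning with VAF
   comparison, the 6-class strand-collapsed substitution spectrum, and the
   nonsilent-to-silent ratio.
4. **Copy number** — binned log2 tumor/normal depth ratios, recursive
   binary segmentation (t-statistic splits), a five-state purity-aware
   caller (state means `log2(1−π)`, `log2(1−π/2)`, `0`, `log2(1+π/2)`,
   `log2(1+π)`), and cross-patient discovery of regions shared or unique to
   primary/recurrent tumors in ≥ k of n patients.
5. **Differential expression** — median-of-ratios size factors, per-patient
   tumor/normal log2 fold changes, a sum-conditioned negative-binomial exact
   test for single tumor/normal pairs (dispersion borrowed from a
   method-of-moments trend `φ(μ) = a₀ + a₁/μ`), and a recurrent-versus-
   non-recurrent Welch contrast on the per-patient folds (`|Δlog2| ≥ 1`,
   raw `p < 0.01`, deliberately unadjusted).
6. **Prognosis** — candidate genes are the intersection of deleted-region
   genes with the under-expressed set; each is dichotomized (median cut, or
   reference mean − 2 SD), then Kaplan–Meier curves, the log-rank test and
   Cox proportional-hazards regression (Newton–Raphson on the Efron partial
   likelihood, Wald CIs, likelihood-ratio test, separation flagged) screen
   for survival association.

Because matched transplant cohorts are rare and small, the package ships a
**synthetic cohort generator** that emulates the full study design — 21
patients, 9 recurrent, 4 sequenced with five specimens each (P_T, P_NAT,
R_T, R_NAT, P_B), Hardy–Weinberg germlines, clonal somatic variants with
binomial read sampling, recurrent tumors as recipient/donor mixtures with
known α, a planted shared hemizygous deletion, NB expression counts with a
planted under-expressed gene, and proportional-hazards recurrence times —
with a ground-truth record for every planted quantity.

## Worked example

```python
from oltrecur import SimulationConfig, generate_cohort, analyze_cohort

config = SimulationConfig(seed=1)      # the default study design
cohort = generate_cohort(config)
result = analyze_cohort(cohort)
```

Iterating over `result.patients` and the candidate-gene survival models
prints (exact output of `seed=1`):

```
HCC01: origin=recipient (CR=0.79), donor contamination 80 % [simulated truth 80%]
HCC02: origin=recipient (CR=0.83), donor contamination 6 % [simulated truth 6%]
HCC03: origin=recipient (CR=0.84), donor contamination 54–55 % [simulated truth 55%]
HCC04: origin=recipient (CR=0.82), donor contamination 0 % [simulated truth 0%]

shared deletions (>= 3 of 4 patients):
chrom    start      end  n_bins
 chr4 40000000 69000000      29

under-expressed in recurrent patients: ['G0174']
candidates (deleted and under-expressed): ['G0174']

G0174: low/high split 11/10, log-rank p = 0.0002 (monotone likelihood: all events in the low group)
planted truth: gene G0174, log2 fold -1.5, hazard ratio 7.0
```

Reading the output: all four recurrent tumors are called recipient-derived;
the two contamination estimators bracket each simulated α (the reporting
range is their envelope); the planted chr4 deletion is recovered as a
shared region; exactly the planted gene survives the deletion ×
under-expression intersection; and its median split (11 low / 10 high among
21 patients) separates recurrence times at log-rank p = 2×10⁻⁴. The Cox
fit is flagged for monotone likelihood rather than suppressed — with every
event in the low group the hazard ratio is unbounded, the expected regime
at n = 21.

The same steps are scriptable from a shell via the `oltrecur` CLI
(`simulate`, `somatic`, `origin`, `contamination`, `cnv`, `regions`, `de`,
`survival`, `screen`); run `oltrecur COMMAND --help` for the file formats.

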