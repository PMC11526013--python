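# Methods

`dxprs` implements the statistical machinery needed to ask whether a
self-reported clinical diagnosis of schizophrenia is a valid case
definition for genomic research: diagnostic concordance between
self-report, research-interview and medical-record sources; genotype
quality control; clumping-and-thresholding polygenic scores; and
liability-scale variance-explained comparisons across case definitions.
Everything runs end-to-end on a synthetic liability-threshold cohort
whose generator is itself first-class, tested code.

## Diagnostic concordance

A participant is *index-positive* for a source if any of their records of
that source falls in the index category set (participants may endorse
several diagnoses), and *assessed* by a reference source if they carry at
least one record of it; assessed-but-negative is encoded as an explicit
`NONE` record. The 2x2 table then yields

- PPV = tp/(tp+fp), NPV = tn/(tn+fn),
- sensitivity = tp/(tp+fn), specificity = tn/(tn+fp).

In a clinically-ascertained design, only index-positive participants were
ever assessed by the reference (interviews were offered to people who
self-reported a diagnosis), so NPV, sensitivity and specificity are
reported as *missing*, never computed from the biased frame. PPV remains
valid.

A population-representative table's PPV/NPV are restated at an external
point prevalence pi by Bayes' rule on the error rates:

    PPV(pi) = sens*pi / (sens*pi + (1-spec)(1-pi))
    NPV(pi) = spec*(1-pi) / (spec*(1-pi) + (1-sens)*pi)

For schizophrenia we default pi = 0.006 (0.6% point prevalence). A
seeded Monte-Carlo population simulation (`simulate_predictive_values`)
provides an independent check of the closed form. ICD-10 codes map to
categories as: F20.* schizophrenia; F25.1 schizoaffective depressed type;
the rest of F21-F29 other psychotic disorders; F30-F39 mood disorders;
anything else `OTHER`.

Reported PPVs are rounded to 2 decimals in report tables; raw values are
always retained in machine output.

## Genotype quality control

Defaults follow common GWAS practice: variants removed at MAF < 0.05,
missingness > 0.05, or exact Hardy-Weinberg p <= 1e-6 (the inequality is
inclusive). The HWE test is the exact conditional test — enumeration of
the heterozygote-count distribution given allele counts, summing
probabilities no larger than the observed table's — computed in log space
so it is stable to totals in the hundreds of thousands; a chi-square
variant is available by config.

LD pruning slides a 500-variant window in 20-variant steps along each
chromosome; while any kept pair in the window has dosage r^2 above 0.2,
the lower-MAF member is dropped (ties drop the later position —
deterministic output). Missing dosages are mean-imputed for all
correlation work, which preserves allele frequency.

Relatedness is estimated on the pruned panel as the correlation-form GRM:
each individual's standardised-dosage vector is scaled to unit norm
before the cross-product. On this IBD-proportion-like scale duplicates
score exactly 1 at any sample size (the plain Z Z'/m GRM shrinks
duplicate pairs by roughly (1-2/n)^2 in small samples, which would defeat
the 0.98 duplicate threshold), first-degree relatives fall near 0.5 and
unrelated pairs near 0. One member of each pair above 0.1875 is removed
by a seeded uniform draw, pairs processed in deterministic index order.
The estimator's pairwise noise has sd ~ 1/sqrt(m) over m pruned variants,
so the panel must keep a few hundred near-independent variants for the
0.1875 threshold to be meaningful — the synthetic generator's default LD
geometry is sized accordingly (see below).

Ancestry clustering computes PCs by SVD of the standardised dosage
matrix, measures each individual's Euclidean distance to the centroid of
the first 5 PC scores, and keeps the ceil(0.9 n) closest individuals.
"Most central point" is read as the centroid (not medoid) and the 90%
rule as a retained fraction (not a distance percentile); both were open
readings and the simpler one is implemented, with the alternative
reachable through the threshold config.

## Polygenic scores

Construction is clumping + thresholding: variants with MAF strictly
above 0.01 outside the extended MHC (chr6:25-34 Mb, GRCh37 convention,
inclusive bounds) are greedily clumped — visiting by ascending p, each
unclaimed variant becomes an index SNP and claims everything unclaimed
within 500 kb at r^2 >= 0.1 — and index SNPs with p <= 0.05 contribute
dosage x log-odds to the score. A single p threshold is used; there is
no threshold search. Missing dosages are imputed as 2x the target-sample
effect-allele frequency. Alleles are matched exactly or swapped with
effect-size negation; no strand flipping is attempted, and palindromic
(A/T, C/G) variants are rejected when no frequency is available to orient
them. Scores are z-standardised within the scored sample.

## Association and liability-scale r^2

Group comparisons are maximum-likelihood logistic regressions
(statsmodels), Wald 95% CIs on the log-odds scale. Phenotype contrasts
between diagnosis-pathway groups covary for year of birth and sex (a
covariate is dropped when it is the outcome or collinear with it, as year
of birth is with age); age enters per decade by default, since per-year
coding makes odds ratios uninterpretable at this granularity; employment
is restricted to participants under 65 not reporting retirement. AUC is
the Mann-Whitney statistic (ties counted half).

Variance explained by a PRS is the incremental pseudo-R^2 of the full
model over a covariates-only baseline. The reported observed-scale value
`r2_obs` is Nagelkerke (Cox-Snell by config). Conversion to the
liability scale uses the ascertainment-corrected transformation for
case-control samples at population risk K (default 1% lifetime risk) and
sample case fraction P: with t the upper-K standard-normal quantile,
z = phi(t), m = z/K,

    C = K(1-K)/z^2 * K(1-K)/(P(1-P))
    theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t)
    r2_liab = C r2 / (1 + C theta r2)

One numerical subtlety: this transformation is derived for the R^2 of
case status on the observed 0/1 scale, which the Cox-Snell increment
approximates closely; the Nagelkerke renormalisation 1/(1-exp(2 ll0/n))
(about 1.33x at P = 0.5) would propagate into the converted value and
systematically overstate liability r^2 by a third. The implementation
therefore converts the Cox-Snell increment, and simulation confirms it
recovers generative liability r^2 in {0.02, 0.05, 0.10} within a few
percent at 1000 cases/1000 controls, while the reported `r2_obs` keeps
the conventional Nagelkerke form. The standard error of `r2_liab` is a
seeded individual-level bootstrap (200 replicates by default). Negative
incremental R^2 is clamped to zero with a warning.

Severity gradients fit each ordinal level (endorsement count, admission
count, primary vs secondary coding) against controls, plus case-only
contrasts between adjacent levels.

## Synthetic cohort generator

The generator defines the study conditions the tests exercise.

- **Genotypes.** Biallelic dosages in compound-symmetry LD blocks: per
  block and haplotype copy a latent standard-normal factor; each
  variant's haplotype allele is a threshold draw from a latent loading
  sqrt(r) on the factor, so within-block latent correlation is r
  (default 0.7) and cross-block LD is null. Allele frequencies are
  uniform on (0.05, 0.5). The default geometry is 2000 variants in
  blocks of 5 — many small blocks rather than few large ones — so that
  after LD pruning several hundred near-independent variants remain and
  the relatedness threshold (see above) operates above its noise floor.
  Dichotomising the latent attenuates dosage r^2 below r^2 of the
  latents; the blocks still exercise pruning (within-block r^2 ~ 0.2-0.4)
  and clumping.
- **Phenotype.** A sparse additive genetic score over n_causal variants
  (standard-normal effects on standardised dosages, rescaled so the
  realised genetic variance equals h2_prs, default 0.05 — the order of
  current schizophrenia PRS performance) plus independent Gaussian noise;
  cases exceed the upper-K quantile (K default 1%).
- **Summary statistics.** Per-allele effects are the standardised effects
  divided by sqrt(2f(1-f)); training noise has SE = 1/sqrt(2f(1-f)
  n_train) with a two-sided Wald p — the sampling behaviour of a
  quantitative-trait GWAS of size n_train on a unit-variance outcome.
- **Diagnosis pathways.** Cases acquire a medical-record diagnosis with
  probability 0.6 (admission count 1 + Poisson(1.5), primary coding with
  probability 0.6), self-report with probability 0.8 given a record and
  0.5 without, endorse the diagnosis twice with probability 0.35, and —
  only if they self-report, mirroring clinically-ascertained recruitment
  — receive a research-interview category drawn from a confusion row.
  The default schizophrenia row (0.70, 0.11, 0.06, 0.13) over
  (schizophrenia, schizoaffective-depressed, other psychotic, mood)
  reproduces the 0.70 / 0.81 / 0.87 concordance ladder in expectation.
  Controls self-report falsely at rate 0.005 and are interview-negative.
  A `liability_slope` parameter couples record capture, endorsement
  repetition, admissions and primary coding monotonically (on the logit
  scale) to the case's liability quantile; 0 disables the coupling.
- **Covariates.** Sex, year of birth, GCSE-level education, degree,
  employment and retirement with logit-scale offsets for the
  reference-diagnosis group (defaults: born 4 years later, +0.48 logits
  GCSE, modest sex/degree/employment offsets — the direction and order of
  the observed group differences); `CovariateEffects.null()` gives
  exchangeable groups.

What the generator does **not** emulate: realistic human LD maps and
recombination (compound-symmetry blocks only), family structure beyond
planted duplicate/relative fixtures, binary-trait training GWAS
(quantitative-trait noise model), genotyping batch effects, and
non-European-ancestry structure. Passing tests therefore demonstrate the
statistical machinery is correct under the liability-threshold model, not
that real-cohort estimates would match.

## Reproducibility and problem sizes

A single master seed expands into fixed per-stage substreams, so every
stage replays identically in isolation; whole-pipeline outputs are
byte-identical across re-runs with the same seed and config. The
end-to-end demonstration profile (600 individuals, 2000 variants,
case-enriched frame with a 35% liability threshold standing in for
clinical ascertainment, n_train 100k) completes in well under a minute.
Property-style checks use: liability-r^2 recovery at 1000 cases/1000
controls x 20 replicates per generative value; null calibration of the
pathway-group PRS test over 400 replicates of 800 cases; severity
monotonicity over 20 replicates of 4000 cases/2000 controls with
liability coupling slope 6 — the published endorsement gradient was
resolved against several hundred thousand controls, so a desk-scale
demonstration of monotone ordering needs this stronger coupling.

## Known limitations

- The exact HWE test assumes founders and autosomal biallelic variants.
- Relatedness removal is pairwise-greedy in deterministic order, not a
  minimum vertex cover; cliques may lose more members than strictly
  necessary.
- PCA is within-sample; no reference-panel projection.
- Dosage-level (imputed) input is accepted but HWE hard-calls dosages by
  rounding.
- The liability transformation assumes the PRS-liability relationship is
  linear and the covariate baseline is shared between models.
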