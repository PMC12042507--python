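# Methods

## The regulatory model

nc886 (vtRNA2-1) is a polymorphically imprinted non-coding RNA locus.  Two
stable regulators determine an individual's lifelong blood levels of the two
processed fragments, nc886-3p and nc886-5p:

1. **Epigenotype.** The differentially methylated region (DMR) covering the
   locus is either methylated on the maternal allele ("imprinted", the
   majority state), unmethylated on both alleles ("non-methylated"), or in a
   heterogeneous intermediate state.  A methylated maternal allele is
   transcriptionally silent.
2. **Genotype.** The downstream SNP rs1799962 (major allele T, minor allele
   C) acts in cis: the minor allele multiplies the output of the allele that
   carries it, so in imprinted individuals it only matters when inherited
   from the father.

The package turns these two measurements into a three-level usage label —
control (imprinted T/T), elevated (all non-methylated groups plus imprinted
C/C), excluded (intermediate groups and imprinted T/C) — and associates the
elevated-vs-control contrast with cardiometabolic phenotypes per cohort,
pooling cohorts by meta-analysis.

## Epigenotype classification

Per individual we take the median beta value over the 11 DMR probes
(cg07158503, cg11608150, cg06478886, cg04481923, cg18678645, cg06536614,
cg25340688, cg26896946, cg00124993, cg08745965, cg18797653) and classify:
imprinted for median ≥ 0.4, intermediate in [0.2, 0.4), non-methylated
below 0.2.  The published thresholds are strict inequalities that leave the
boundary points unassigned; we resolve them with half-open intervals (0.4 →
imprinted, 0.2 → intermediate), a choice that is configurable and affects
essentially no real sample because the empirical distribution is trimodal
with mass far from the cut points.  Three further bimodal probes
(cg04515200, cg13581155, cg11978884) are hypomethylation-biased and are
rejected if passed in a probe list unless explicitly allowed.  A sample
needs at least 6 of the 11 probes (configurable) for a call; otherwise it is
`unknown` and excluded with a recorded reason.

## Parent-of-origin inference

For a heterozygous child the trio call enumerates which parental
transmissions can produce the child's genotype, treating a missing parent as
unconstrained.  Mendelian consistency is checked first and violations are
reported, never dropped.  The origin is returned whenever it is forced — in
particular a single observed T/T parent forces the other lineage — while
double-heterozygous trios are `ambiguous` (we do not phase probabilistically)
and undecidable-with-missing-parent trios are `unknown`.  Only `maternal` /
`paternal` calls feed the expression contrast.

Imprinted heterozygotes are excluded from the association proxy even when
their origin is known, because origin is unresolvable for the bulk of real
cohort samples; the `pofo_rescue` flag (default off) reassigns resolved
carriers (paternal → elevated, maternal → control) for sensitivity analyses.

## Expression

Relative expression follows the delta-delta-Cq convention, 2^−(Cq − median
reference Cq), with imprinted individuals as the reference.  Group fold
changes are ratios of medians by default (robust, and consistent with the
median-anchored reference; a means-ratio option exists), with Welch's t on
log2 values as the default two-group test and Mann–Whitney as an
alternative — the published contrasts do not name their test, so we do not
treat any particular p-value as a target.  Bimodality screening fits one-
and two-component equal-variance Gaussian mixtures on log2 expression and
flags bimodality when BIC prefers two components and the means are ≥ 0.5
log2 units apart; the equal-variance constraint stops the second component
from modelling a heavy tail instead of a mode.

## Association models

Continuous outcomes are rank-based inverse-normal transformed (Blom offset
c = 3/8, average ranks for ties — the common GWAS/EWAS convention; the
transform is applied within the analysed stratum) and fitted by OLS with
age, sex and fasting as covariates.  Binary outcomes are fitted by
maximum-likelihood logistic regression (Newton/IRLS, convergence tolerance
1e−10) adjusted for age and sex, with Wald standard errors and
exp(β ± 1.96·se) intervals; outcomes with ≤ 10 cases are skipped with a
recorded reason, and separation raises an explicit error.  Sex-stratified
fits drop the sex covariate.  Missing data are handled complete-case per
model, with dropped-row counts reported.  Benjamini–Hochberg FDR is applied
within each (cohort, stratum, model-type) family.

## Meta-analysis

Fixed effects (weights 1/se²) for continuous outcomes; DerSimonian–Laird
random effects for binary outcomes, pooled on the log-OR scale and also
reported as OR.  DL is the default τ² estimator because it is closed-form
and exactly testable against a hand computation; an REML estimator
(bounded restricted-likelihood search, validated against R's metafor) is
available via `random_effects(..., method="reml")` as a sensitivity
option, since the two differ only under between-cohort heterogeneity.
Longitudinal cohorts contribute exactly one timepoint to a
pooling run; timepoint selection is a configuration concern upstream of the
pooling layer.

## The synthetic-cohort generator

Real data at this locus are access-restricted, so the generator emulates the
study conditions and is itself first-class, tested code.

* **Epigenotypes** are drawn from (0.732, 0.032, 0.236) — the published
  frequency column of the largest genotyped cohort.
* **Methylation** betas are Beta-distributed per epigenotype with means
  0.50 / 0.30 / 0.05 and concentration 200 (Beta(100,100), Beta(60,140),
  Beta(10,190)).  The published material specifies thresholds, not beta
  distributions; the concentration is chosen so that well under 0.5% of
  imprinted draws fall below the 0.4 cut, matching the clean trimodal
  separation seen in real cohorts.
* **Genotypes**: maternal and paternal alleles are independent
  Bernoulli(MAF) draws with MAF 0.0992, derived from the published genotype
  frequencies (17.4% T/C + 2×1.0% C/C over 2 alleles); this yields
  Hardy–Weinberg proportions by construction.  Parents are emitted by
  fixing the transmitted allele and drawing the untransmitted one from the
  population, so trios are always Mendelian-consistent.
* **Expression** is additive over alleles: each allele contributes its
  methylation-dependent activity (maternal: 0 if imprinted, 0.5 if
  intermediate, 1 if non-methylated; paternal: 1) times a multiplicative
  minor-allele factor, 2.18 for nc886-3p and 1.76 for nc886-5p — the
  imprinted-heterozygote parent-of-origin contrasts, which are the cleanest
  published single-stratum effects.  The overall het-vs-major-homozygote
  fold changes (≈2.3/1.7) mix methylation strata and are reproduced only
  approximately; calibrating jointly to all printed fold changes is
  over-determined with two parameters per species, and we privilege the
  parent-of-origin contrasts.  Multiplicative log-normal noise with log2-sd
  0.5 (a typical qPCR-scale spread; the source gives no noise model) is
  applied per species.  The intermediate group's maternal activity of 0.5
  is a neutral placeholder — the group is excluded downstream.
* **Phenotypes**: covariates are age ~ U(30, 45), sex ~ Bernoulli(0.5)
  (code 1 = women), fasting ~ Bernoulli(0.9).  Continuous outcomes are
  standard normal plus a configured standardized shift for elevated
  samples; binary outcomes follow a logistic model with configured baseline
  prevalence and log OR.  Default non-zero effects are the published pooled
  estimates: diastolic BP +0.067 SD, HDL cholesterol −0.066 SD, type 2
  diabetes log(1.26); all other outcomes default to null.  Default
  prevalences: hypertension 0.30, type 2 diabetes 0.10, stroke 0.10, death
  0.20.
* **Seeds**: one seed per cohort config; component streams (epigenotype,
  methylation, alleles, parents, expression, phenotypes) are independent
  SeedSequence children, so toggling one component never perturbs another.
  `multicohort_configs` derives per-cohort seeds (kept below 2³¹) from a
  master seed keyed by cohort position, so adding a cohort does not disturb
  existing ones.

What the generator deliberately does **not** emulate: array technical
artifacts (probe bias, batch effects, 450K/EPIC differences), genotyping or
imputation error, covariate–outcome confounding (age/sex/fasting have no
true effect on outcomes, so covariate adjustment is exercised but never
load-bearing), medication effects, and cross-timepoint correlation in
longitudinal cohorts.  Passing recovery tests therefore demonstrates that
the pipeline's estimators are unbiased and calibrated under the stated
model, not that real cohorts are free of those complications.

## Numerical choices and degenerate inputs

* Display percentages round half-up to 2 decimals; analytic fractions are
  kept unrounded.
* OLS p-values use the t distribution with n − rank degrees of freedom; a
  perfect fit (zero residual variance) is flagged rather than reported with
  a spurious p.
* Rank-deficient designs raise a collinearity error naming the columns
  whose removal restores full rank.
* The inverse-normal transform requires ≥ 2 non-missing values; an
  all-tied vector maps to all zeros (mid-rank).
* DL τ² is truncated at zero, which makes random effects coincide exactly
  with fixed effects when Q ≤ k − 1.
* Fold changes require strictly positive values; empty contrast groups are
  named in the error.

## Problem sizes used in the shipped analyses

The recovery analyses simulate the six-cohort design at the published
analysis sizes (1497, 504, 2183, 1653, 658, 792; total 7287), averaging
pooled estimates over 20 replicate seeds; the parent-of-origin contrast
uses one cohort of 20,000 with parents emitted, which yields ≈2300
origin-resolved imprinted heterozygotes — comfortably above the 2000 the
contrast is specified at, while keeping a full run under a minute.  Type-I
error calibration uses 1000 null replicates of n = 500 per model.

## Known limitations

* The proxy treats all elevated subgroups as one class, although minor
  allele homozygotes with a non-methylated locus plausibly express most;
  dose–response modelling is out of scope, as in the source analysis.
* Survival outcomes are represented only as binary death indicators; no
  time-to-event modelling.
* The VCF helper extracts a single biallelic variant; no phasing or
  multi-variant haplotypes.
* No array preprocessing or normalization: inputs are assumed to be
  already-normalized beta values, which published work shows does not
  affect this locus's clustering.
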