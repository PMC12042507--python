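# nc886proxy

Predicting lifelong nc886 (vtRNA2-1) RNA levels from DNA methylation and
genotype, and testing whether the predicted levels associate with
cardiometabolic health.

## The problem

nc886 is a polymorphically imprinted non-coding RNA: in roughly three
quarters of people of European ancestry the maternal allele of the locus is
methylated and silenced, while most of the rest carry two unmethylated,
transcribing alleles.  On top of this, the downstream SNP rs1799962
(major allele T, minor allele C) acts in cis — the minor allele upregulates
the allele that carries it, so in imprinted individuals it only matters when
inherited from the father.  Because both regulators are established early
and are temporally stable, the pair (epigenotype, genotype) is a proxy for
an individual's lifelong nc886 RNA exposure, usable in cohorts that have
methylation arrays and genotypes but no RNA measurements.

`nc886proxy` implements the full analysis pipeline for epidemiologists and
epigeneticists working with such cohorts:

1. **Epigenotype classification** — median beta over the 11 DMR CpG probes;
   imprinted (β ≥ 0.4), intermediate (0.2 ≤ β < 0.4), non-methylated
   (β < 0.2).
2. **Trio parent-of-origin inference** — Mendelian resolution of which
   parent transmitted the minor allele, with Mendelian-error reporting.
3. **Proxy construction** — the 9 epigenotype × genotype groups collapse to
   control (imprinted T/T), elevated (non-methylated groups + imprinted
   C/C) and excluded (intermediate groups + imprinted T/C).
4. **Expression analytics** — ΔΔCq relative expression, ratio-of-medians
   fold changes, the paternal-vs-maternal origin contrast, and a
   mixture-model bimodality screen.
5. **Association** — per cohort: inverse-normal-transformed linear models
   (age/sex/fasting-adjusted) for continuous outcomes, logistic models
   (age/sex-adjusted, > 10 cases required) for binary outcomes, BH-FDR per
   cohort/stratum/model family, sex-stratified variants.
6. **Meta-analysis** — fixed effects for continuous outcomes,
   DerSimonian–Laird random effects for binary outcomes, with Cochran's Q,
   τ² and forest-plot tables.
7. **Synthetic cohorts** — a generator encoding the regulatory model
   (trimodal methylation, HWE genotypes with phased parental origin,
   maternal-allele silencing, multiplicative cis effects, small phenotype
   effects), so the entire pipeline is testable although the real cohort
   data are access-restricted.

## Worked example

```python
import nc886proxy as nc
from nc886proxy import association

cohort = nc.simulate_cohort(nc.SimulationConfig(n_individuals=2000, seed=7))

calls, proportions = nc.classify_cohort(cohort.methylation)
# proportions: imprinted 0.728, intermediate 0.036, non_methylated 0.235

pofo, tally = nc.call_pofo_cohort(
    cohort.genotypes[["sample_id", "genotype", "mother_genotype", "father_genotype"]]
)
# tally: not_applicable 1650, maternal 181, paternal 139, ambiguous 30

assignments = nc.assign_cohort(calls, cohort.genotypes)
groups, usage = nc.frequency_table(assignments)
#    usage  count  percent
#  control   1174    58.70
# elevated    485    24.25
# excluded    341    17.05

fc = nc.pofo_expression_contrast(cohort.expression, pofo, calls, "nc886_3p")
# fc.fc = 2.07 (114 paternal vs 133 maternal carriers, p = 1.9e-43)

results, skipped = association.run_cohort_associations(
    assignments, cohort.phenotypes,
    continuous_outcomes=("diastolic_bp", "hdl_cholesterol"),
    binary_outcomes=("type2_diabetes",), strata=("all",),
)
#         outcome    model  estimate      se       p       n    or
#    diastolic_bp   linear    0.0458  0.0540  0.3959    1659     -
# hdl_cholesterol   linear   -0.0417  0.0538  0.4387    1659     -
#  type2_diabetes logistic    0.2913  0.1645  0.0767    1659  1.338
```

Reading the output: the cohort splits into the expected ~73/3/24%
epigenotype mixture; among imprinted heterozygotes with trio-resolved
origin, paternal-origin minor-allele carriers express about twice as much
nc886-3p as maternal-origin carriers (the cis-action signature); and the
elevated-vs-control proxy contrast shows the configured small positive
shift in diastolic blood pressure and excess type-2-diabetes odds, neither
of which reaches significance at n = 2000 — detecting effects of this size
is precisely why multiple cohorts are pooled by meta-analysis.

The same stages are scriptable via the CLI
(`nc886proxy simulate | classify | pofo | proxy | expression-fc | assoc |
meta | run | validate`); `nc886proxy run --config pipeline.yaml --out
run_dir` executes everything and writes a manifest with input checksums for
reproducibility.

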