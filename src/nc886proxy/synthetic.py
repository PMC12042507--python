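"""Synthetic cohorts embodying the nc886 regulatory model.

Real cohort data for this locus are access-restricted, so every downstream
stage is exercised on simulated cohorts that encode the locus's known
biology:

* a trimodal methylation mixture over the 11 DMR probes (imprinted /
  intermediate / non-methylated epigenotypes);
* rs1799962 alleles drawn independently per parental chromosome at the
  minor-allele frequency (Hardy-Weinberg genotypes), with parental
  genotypes emitted consistently with the transmitted alleles;
* allele-additive expression: each allele contributes its transcriptional
  activity (maternal allele silenced when imprinted, partially active when
  intermediate) times a multiplicative minor-allele effect, with log-normal
  measurement noise;
* small phenotype effects of the elevated-vs-control proxy contrast —
  standardized mean shifts for continuous outcomes, log odds ratios for
  binary outcomes.

Default parameter values reproduce the published cohort frequency table and
parent-of-origin expression contrasts; see ``docs/methods.md`` for the
calibration rationale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .methylation import DMR_PROBES, IMPRINTED, INTERMEDIATE, NON_METHYLATED
from .proxy import ELEVATED, usage_label

#: Analysis sample sizes of the six cohorts pooled in the meta-analysis
#: (YFS 2007, DILGOM, LURIC, KORA F4, Bogalusa, NFBC1966).
COHORT_SIZES: dict[str, int] = {
    "YFS2007": 1497,
    "DILGOM": 504,
    "LURIC": 2183,
    "KORA_F4": 1653,
    "Bogalusa": 658,
    "NFBC1966": 792,
}

CONTINUOUS_OUTCOMES: tuple[str, ...] = (
    "systolic_bp",
    "diastolic_bp",
    "total_cholesterol",
    "hdl_cholesterol",
    "non_hdl_cholesterol",
    "ldl_cholesterol",
    "glucose",
    "insulin",
)
BINARY_OUTCOMES: tuple[str, ...] = (
    "hypertension",
    "type2_diabetes",
    "stroke",
    "death",
)

#: Published pooled effect sizes used as generator defaults: standardized
#: mean differences for continuous outcomes, log odds ratios for binary.
DEFAULT_PHENOTYPE_EFFECTS: dict[str, float] = {
    "diastolic_bp": 0.067,
    "hdl_cholesterol": -0.066,
    "type2_diabetes": math.log(1.26),
}

DEFAULT_BINARY_PREVALENCE: dict[str, float] = {
    "hypertension": 0.30,
    "type2_diabetes": 0.10,
    "stroke": 0.10,
    "death": 0.20,
}

#: Beta(a, b) parameters per epigenotype: means 0.50 / 0.30 / 0.05 with
#: concentration 200, tight enough that <0.5% of imprinted medians fall
#: below the 0.4 threshold (clean trimodal separation).
DEFAULT_BETA_PARAMS: dict[str, tuple[float, float]] = {
    IMPRINTED: (100.0, 100.0),
    INTERMEDIATE: (60.0, 140.0),
    NON_METHYLATED: (10.0, 190.0),
}

#: Multiplicative expression effect of the minor allele on a transcribing
#: allele, per RNA species (the imprinted-heterozygote paternal-vs-maternal
#: contrasts).
DEFAULT_MINOR_ALLELE_FC: dict[str, float] = {"nc886_3p": 2.18, "nc886_5p": 1.76}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator, with literature-calibrated defaults."""

    n_individuals: int = 1000
    seed: int = 0
    cohort_id: str = "cohort"
    #: P(imprinted), P(intermediate), P(non-methylated)
    epistatus_probs: tuple[float, float, float] = (0.732, 0.032, 0.236)
    minor_allele_freq: float = 0.0992
    beta_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BETA_PARAMS)
    )
    paternal_minor_fc: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MINOR_ALLELE_FC)
    )
    #: residual activity of the maternal allele in intermediate epigenotypes
    intermediate_silencing: float = 0.5
    #: log2-scale SD of multiplicative expression noise
    expression_noise_sd: float = 0.5
    phenotype_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_EFFECTS)
    )
    binary_baseline_prev: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BINARY_PREVALENCE)
    )
    age_range: tuple[float, float] = (30.0, 45.0)
    #: probability of sex code 1 (women)
    sex_ratio: float = 0.5
    fasting_prob: float = 0.9
    emit_parents: bool = True

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")
        probs = np.asarray(self.epistatus_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or np.any(probs > 1):
            raise ConfigError("epistatus_probs must be three probabilities in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigError(f"epistatus_probs must sum to 1, got {probs.sum()!r}")
        for name, p in (
            ("minor_allele_freq", self.minor_allele_freq),
            ("sex_ratio", self.sex_ratio),
            ("fasting_prob", self.fasting_prob),
            ("intermediate_silencing", self.intermediate_silencing),
        ):
            if not 0 <= p <= 1:
                raise ConfigError(f"{name} must lie in [0, 1], got {p}")
        for species, fc in self.paternal_minor_fc.items():
            if fc <= 0:
                raise ConfigError(f"paternal_minor_fc[{species!r}] must be positive")
        for status in (IMPRINTED, INTERMEDIATE, NON_METHYLATED):
            if status not in self.beta_params:
                raise ConfigError(f"beta_params missing epigenotype {status!r}")
            a, b = self.beta_params[status]
            if a <= 0 or b <= 0:
                raise ConfigError("beta_params shapes must be positive")
        if self.expression_noise_sd < 0:
            raise ConfigError("expression_noise_sd must be non-negative")
        for outcome, prev in self.binary_baseline_prev.items():
            if not 0 < prev < 1:
                raise ConfigError(f"baseline prevalence for {outcome} must be in (0, 1)")
        if not self.age_range[0] <= self.age_range[1]:
            raise ConfigError("age_range must be ordered")


@dataclass(frozen=True)
class SyntheticCohort:
    """One simulated cohort: the four data sheets plus the latent truth."""

    cohort_id: str
    methylation: pd.DataFrame  # index sample_id, columns = DMR probes
    genotypes: pd.DataFrame
    expression: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig


def _allele_activity(
    status: np.ndarray, allele_is_minor: np.ndarray, maternal: bool, fc: float,
    intermediate_silencing: float,
) -> np.ndarray:
    """Transcriptional contribution of one allele.

    A transcribing major allele contributes 1; a transcribing minor allele
    contributes ``fc``.  Maternal alleles are fully silenced when imprinted
    and attenuated to ``intermediate_silencing`` when intermediate.
    """
    base = np.where(allele_is_minor, fc, 1.0)
    if not maternal:
        return base
    silencing = np.select(
        [status == IMPRINTED, status == INTERMEDIATE],
        [0.0, intermediate_silencing],
        default=1.0,
    )
    return base * silencing


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one cohort from the configured regulatory model.

    Identical configs (including seed) give identical cohorts.  Independent
    child random streams are used for each component (epigenotype,
    methylation, alleles, parents, expression, phenotypes) so toggling one
    component does not perturb the draws of another.
    """
    config.validate()
    n = config.n_individuals
    streams = np.random.SeedSequence(config.seed).spawn(6)
    rng_status, rng_meth, rng_allele, rng_parent, rng_expr, rng_pheno = (
        np.random.default_rng(s) for s in streams
    )

    sample_ids = [f"{config.cohort_id}_{i:06d}" for i in range(1, n + 1)]

    status = rng_status.choice(
        [IMPRINTED, INTERMEDIATE, NON_METHYLATED], size=n, p=config.epistatus_probs
    )

    # methylation: 11 probes per sample from the epigenotype's Beta law
    betas = np.empty((n, len(DMR_PROBES)))
    for st, (a, b) in config.beta_params.items():
        mask = status == st
        if mask.any():
            betas[mask] = rng_meth.beta(a, b, size=(int(mask.sum()), len(DMR_PROBES)))
    methylation = pd.DataFrame(betas, index=pd.Index(sample_ids, name="sample_id"),
                               columns=list(DMR_PROBES))

    # alleles: one maternal and one paternal chromosome per child
    maf = config.minor_allele_freq
    maternal_minor = rng_allele.random(n) < maf
    paternal_minor = rng_allele.random(n) < maf
    n_minor = maternal_minor.astype(int) + paternal_minor.astype(int)
    genotype = np.array(["TT", "TC", "CC"])[n_minor]

    # parents: the transmitted allele is fixed, the untransmitted allele is a
    # fresh population draw, so trios are always Mendelian-consistent
    def parent_genotype(transmitted_minor: np.ndarray) -> np.ndarray:
        other_minor = rng_parent.random(n) < maf
        counts = transmitted_minor.astype(int) + other_minor.astype(int)
        return np.array(["TT", "TC", "CC"])[counts]

    mother_genotype = parent_genotype(maternal_minor)
    father_genotype = parent_genotype(paternal_minor)

    genotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "genotype": genotype,
            "maternal_allele": np.where(maternal_minor, "C", "T"),
            "paternal_allele": np.where(paternal_minor, "C", "T"),
            "mother_genotype": mother_genotype if config.emit_parents else pd.NA,
            "father_genotype": father_genotype if config.emit_parents else pd.NA,
        }
    )

    # expression: additive over allele activities, log-normal noise per species
    expression = pd.DataFrame({"sample_id": sample_ids})
    for species, fc in config.paternal_minor_fc.items():
        total = _allele_activity(
            status, maternal_minor, True, fc, config.intermediate_silencing
        ) + _allele_activity(
            status, paternal_minor, False, fc, config.intermediate_silencing
        )
        noise = (
            2.0 ** rng_expr.normal(0.0, config.expression_noise_sd, size=n)
            if config.expression_noise_sd > 0
            else 1.0
        )
        expression[species] = total * noise

    # phenotypes: covariates plus outcome columns shifted for elevated samples
    usage = np.array([usage_label(s, g)[0] for s, g in zip(status, genotype)])
    elevated = (usage == ELEVATED).astype(float)
    phenotypes = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": rng_pheno.uniform(*config.age_range, size=n),
            "sex": (rng_pheno.random(n) < config.sex_ratio).astype(int),
            "fasting": (rng_pheno.random(n) < config.fasting_prob).astype(int),
        }
    )
    for outcome in CONTINUOUS_OUTCOMES:
        shift = config.phenotype_effects.get(outcome, 0.0)
        phenotypes[outcome] = rng_pheno.standard_normal(n) + shift * elevated
    for outcome in BINARY_OUTCOMES:
        prev = config.binary_baseline_prev.get(outcome, 0.1)
        log_or = config.phenotype_effects.get(outcome, 0.0)
        logit = math.log(prev / (1 - prev)) + log_or * elevated
        p = 1.0 / (1.0 + np.exp(-logit))
        phenotypes[outcome] = (rng_pheno.random(n) < p).astype(int)

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "epistatus": status,
            "maternal_allele": np.where(maternal_minor, "C", "T"),
            "paternal_allele": np.where(paternal_minor, "C", "T"),
            "genotype": genotype,
            "usage": usage,
        }
    )

    return SyntheticCohort(
        cohort_id=config.cohort_id,
        methylation=methylation,
        genotypes=genotypes,
        expression=expression,
        phenotypes=phenotypes,
        truth=truth,
        config=config,
    )


def simulate_multicohort(configs: list[SimulationConfig]) -> list[SyntheticCohort]:
    """Simulate several independent cohorts (one per config)."""
    if not configs:
        raise ConfigError("at least one cohort config is required")
    return [simulate_cohort(c) for c in configs]


def multicohort_configs(
    seed: int,
    sizes: dict[str, int] | None = None,
    **overrides,
) -> list[SimulationConfig]:
    """Default six-cohort study design with per-cohort seeds derived from one
    master seed.

    Child seeds come from a :class:`numpy.random.SeedSequence` spawn keyed by
    cohort position, so adding a cohort never perturbs the draws of existing
    ones.  ``overrides`` are applied to every cohort's config.
    """
    sizes = sizes or COHORT_SIZES
    children = np.random.SeedSequence(seed).spawn(len(sizes))
    configs = []
    for (cohort_id, n), child in zip(sizes.items(), children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        configs.append(
            SimulationConfig(
                n_individuals=n, seed=child_seed, cohort_id=cohort_id, **overrides
            )
        )
    return configs
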