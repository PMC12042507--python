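import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from nc886proxy import (
    COHORT_SIZES,
    SimulationConfig,
    multicohort_configs,
    simulate_cohort,
    simulate_multicohort,
)
from nc886proxy.errors import ConfigError
from nc886proxy.methylation import IMPRINTED, INTERMEDIATE, NON_METHYLATED


class TestConfigValidation:
    def test_zero_individuals(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_individuals=0).validate()

    def test_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(epistatus_probs=(0.5, 0.2, 0.2)).validate()

    def test_probability_range(self):
        with pytest.raises(ConfigError):
            SimulationConfig(minor_allele_freq=1.5).validate()

    def test_fold_change_must_be_positive(self):
        with pytest.raises(ConfigError):
            SimulationConfig(paternal_minor_fc={"nc886_3p": -1.0, "nc886_5p": 1.0}).validate()


class TestDegenerateModels:
    def test_forced_imprinted_major_homozygotes_express_exactly_one(self):
        """Only the paternal T allele transcribes: expression is exactly 1."""
        config = SimulationConfig(
            n_individuals=50,
            epistatus_probs=(1.0, 0.0, 0.0),
            minor_allele_freq=0.0,
            expression_noise_sd=0.0,
        )
        cohort = simulate_cohort(config)
        assert (cohort.truth["epistatus"] == IMPRINTED).all()
        assert (cohort.genotypes["genotype"] == "TT").all()
        for species in ("nc886_3p", "nc886_5p"):
            assert cohort.expression[species].tolist() == pytest.approx([1.0] * 50)

    def test_forced_non_methylated_express_exactly_two(self):
        """Both T alleles transcribe: expression is exactly 2."""
        config = SimulationConfig(
            n_individuals=50,
            epistatus_probs=(0.0, 0.0, 1.0),
            minor_allele_freq=0.0,
            expression_noise_sd=0.0,
        )
        cohort = simulate_cohort(config)
        for species in ("nc886_3p", "nc886_5p"):
            assert cohort.expression[species].tolist() == pytest.approx([2.0] * 50)

    def test_noise_free_expression_matches_latent_state_enumeration(self):
        """Without noise, expression is a pure function of the 12 latent
        (epigenotype, maternal allele, paternal allele) states; enumerate
        the allele-activity products by brute force and compare."""
        config = SimulationConfig(
            n_individuals=3000, seed=5, expression_noise_sd=0.0, minor_allele_freq=0.4
        )
        cohort = simulate_cohort(config)
        silencing = {IMPRINTED: 0.0, INTERMEDIATE: config.intermediate_silencing,
                     NON_METHYLATED: 1.0}
        for species, fc in config.paternal_minor_fc.items():
            expected_by_state = {}
            for status, mat, pat in itertools.product(silencing, "TC", "TC"):
                maternal = (fc if mat == "C" else 1.0) * silencing[status]
                paternal = fc if pat == "C" else 1.0
                expected_by_state[(status, mat, pat)] = maternal + paternal
            observed = cohort.expression[species].to_numpy()
            states = list(
                zip(
                    cohort.truth["epistatus"],
                    cohort.truth["maternal_allele"],
                    cohort.truth["paternal_allele"],
                )
            )
            expected = np.array([expected_by_state[s] for s in states])
            assert observed == pytest.approx(expected)
            # the 12 latent states collapse onto the enumerated products
            enumerated = {round(v, 12) for v in expected_by_state.values()}
            assert set(np.round(observed, 12)) <= enumerated


class TestCohortStructure:
    def test_sample_ids_agree_across_tables(self):
        cohort = simulate_cohort(SimulationConfig(n_individuals=30, seed=1))
        ids = list(cohort.methylation.index)
        for table in (cohort.genotypes, cohort.expression, cohort.phenotypes, cohort.truth):
            assert list(table["sample_id"]) == ids

    def test_counts_are_conserved(self):
        cohort = simulate_cohort(SimulationConfig(n_individuals=500, seed=2))
        assert cohort.truth["epistatus"].value_counts().sum() == 500
        n_minor = cohort.genotypes["genotype"].map({"TT": 0, "TC": 1, "CC": 2}).sum()
        n_major = 2 * 500 - n_minor
        assert n_minor + n_major == 1000

    def test_expression_is_strictly_positive(self):
        cohort = simulate_cohort(SimulationConfig(n_individuals=500, seed=3))
        assert (cohort.expression[["nc886_3p", "nc886_5p"]] > 0).all().all()

    def test_child_alleles_consistent_with_parents(self):
        cohort = simulate_cohort(SimulationConfig(n_individuals=2000, seed=4))
        merged = cohort.genotypes.merge(cohort.truth, on="sample_id", suffixes=("", "_t"))
        for row in merged.itertuples():
            assert row.maternal_allele in row.mother_genotype
            assert row.paternal_allele in row.father_genotype

    def test_parents_can_be_suppressed(self):
        cohort = simulate_cohort(SimulationConfig(n_individuals=20, seed=5, emit_parents=False))
        assert cohort.genotypes["mother_genotype"].isna().all()


class TestDeterminismAndSeeds:
    def test_identical_seed_reproduces_cohort_exactly(self):
        a = simulate_cohort(SimulationConfig(n_individuals=200, seed=7))
        b = simulate_cohort(SimulationConfig(n_individuals=200, seed=7))
        pd.testing.assert_frame_equal(a.methylation, b.methylation)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(n_individuals=200, seed=7))
        b = simulate_cohort(SimulationConfig(n_individuals=200, seed=8))
        assert not a.methylation.equals(b.methylation)

    def test_multicohort_is_reproducible_and_independent(self):
        configs = [
            SimulationConfig(n_individuals=100, seed=1, cohort_id="a"),
            SimulationConfig(n_individuals=100, seed=2, cohort_id="b"),
        ]
        first = simulate_multicohort(configs)
        second = simulate_multicohort(configs)
        for x, y in zip(first, second):
            pd.testing.assert_frame_equal(x.expression, y.expression)
        # singleton call matches element of the pair
        single = simulate_cohort(configs[0])
        pd.testing.assert_frame_equal(single.expression, first[0].expression)

    def test_empty_multicohort_is_an_error(self):
        with pytest.raises(ConfigError):
            simulate_multicohort([])

    def test_study_design_sizes(self):
        configs = multicohort_configs(seed=0)
        cohorts = simulate_multicohort(configs)
        assert [c.config.n_individuals for c in cohorts] == [1497, 504, 2183, 1653, 658, 792]
        assert {c.cohort_id for c in cohorts} == set(COHORT_SIZES)
        # derived child seeds stay in the 32-bit range
        assert all(0 <= c.config.seed < 2**31 for c in cohorts)


class TestPopulationGenetics:
    def test_genotypes_follow_hardy_weinberg(self):
        """Observed genotype counts at n=50000 are compatible with p^2 /
        2pq / q^2 (chi-square goodness of fit, alpha = 0.001)."""
        config = SimulationConfig(n_individuals=50000, seed=13, minor_allele_freq=0.0992)
        cohort = simulate_cohort(config)
        counts = cohort.genotypes["genotype"].value_counts()
        q = config.minor_allele_freq
        p = 1 - q
        expected = 50000 * np.array([p**2, 2 * p * q, q**2])
        observed = np.array([counts.get(g, 0) for g in ("TT", "TC", "CC")])
        stat, pvalue = chisquare(observed, expected)
        assert pvalue > 0.001

    def test_default_cohort_frequencies_match_published_table(self, default_cohort, default_calls):
        """At n=20000 the classified epigenotype fractions and genotype
        frequencies reproduce the published cohort column (73.2% imprinted,
        81.6% T/T) within binomial sampling error."""
        _, proportions = default_calls
        assert proportions[IMPRINTED] == pytest.approx(0.732, abs=0.01)
        assert proportions[NON_METHYLATED] == pytest.approx(0.236, abs=0.01)
        geno = default_cohort.genotypes["genotype"].value_counts(normalize=True)
        assert geno["TT"] == pytest.approx(0.816, abs=0.01)
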