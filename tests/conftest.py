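import pytest

from nc886proxy import SimulationConfig, classify_cohort, call_pofo_cohort, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One large default-parameter cohort shared by the statistical tests."""
    return simulate_cohort(SimulationConfig(n_individuals=20000, seed=42))


@pytest.fixture(scope="session")
def default_calls(default_cohort):
    calls, proportions = classify_cohort(default_cohort.methylation)
    return calls, proportions


@pytest.fixture(scope="session")
def default_pofo(default_cohort):
    calls, tally = call_pofo_cohort(
        default_cohort.genotypes[
            ["sample_id", "genotype", "mother_genotype", "father_genotype"]
        ]
    )
    return calls, tally
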