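import numpy as np
import pytest

from drugsense import synthetic, training


@pytest.fixture(scope="session")
def small_benchmark():
    """A small planted-biomarker training panel shared across tests."""
    return synthetic.simulate_benchmark(
        n_genes=500,
        n_cell_lines=60,
        n_drugs=8,
        n_biomarkers_per_direction=25,
        effect_beta=2.0,
        noise_sd=1.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def small_library(small_benchmark):
    return training.build_library(
        small_benchmark.expression, small_benchmark.response, lineage_label="synthetic"
    )


@pytest.fixture(scope="session")
def small_cohort(small_benchmark):
    return synthetic.simulate_cohort(
        small_benchmark,
        n_patients_per_subtype=3,
        drugs_per_subtype=2,
        shift=2.0,
        seed=102,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
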