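import numpy as np
import pytest

from perturbsem import all_pairs_design, benchmark_sem, simulate


@pytest.fixture(scope="session")
def sem():
    return benchmark_sem()


@pytest.fixture(scope="session")
def noiseless_data(sem):
    quiet = benchmark_sem()
    quiet.noise_sd = 0.0
    design = all_pairs_design(quiet.q, drug_names=quiet.drug_names)
    return simulate(quiet, design, seed=0)


@pytest.fixture(scope="session")
def noisy_data(sem):
    design = all_pairs_design(sem.q, drug_names=sem.drug_names)
    return simulate(sem, design, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
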