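import pytest

from genomescape.reference import toy_genome
from genomescape.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def toy_ref():
    return toy_genome()


@pytest.fixture(scope="session")
def small_cohort():
    """12 samples with default (study-condition) settings, fixed seed."""
    cfg = SimulationConfig(seed=11, n_samples=12)
    profiles, truth = simulate_cohort(cfg)
    return cfg, profiles, truth


@pytest.fixture(scope="session")
def recovery_cohort():
    """40 samples at the default 60% chromothripsis prevalence."""
    cfg = SimulationConfig(seed=1, n_samples=40)
    profiles, truth = simulate_cohort(cfg)
    return cfg, profiles, truth
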