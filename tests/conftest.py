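import numpy as np
import pytest

from vfaquant import GeneratorConfig, cohort_frame, sample_cohort, simulate_features


@pytest.fixture()
def config() -> GeneratorConfig:
    return GeneratorConfig(seed=11)


@pytest.fixture(scope="session")
def small_cohort_tables():
    """Features + truth for a 40-patient cohort (duplicates), default noise."""
    config = GeneratorConfig(seed=23, n_patients=40)
    rng = config.rng()
    samples = sample_cohort(config, rng)
    truth = cohort_frame(samples)
    features = simulate_features(samples, config, rng)
    return features, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
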