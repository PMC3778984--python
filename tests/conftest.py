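import dataclasses

import numpy as np
import pytest

from fcrkit import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def noiseless_config() -> GeneratorConfig:
    """All noise sources off: the pipeline must recover latent truth exactly."""
    return GeneratorConfig(
        n_subjects=5, seed=11, emg_noise_sd=0.0, fa_noise_sd=0.0,
        fm_noise_sd=0.0, walk_speed_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return generate_cohort(noiseless_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def replace(cfg: GeneratorConfig, **kw) -> GeneratorConfig:
    return dataclasses.replace(cfg, **kw)
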