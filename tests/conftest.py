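import pytest
from hypothesis import HealthCheck, settings

import comorbnet as cn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_dataset():
    """One generated dataset at the default study conditions (seed 1)."""
    cfg = cn.GeneratorConfig(seed=1)
    persons, events, deaths, truth = cn.generate_dataset(cfg)
    return cfg, persons, events, deaths, truth


@pytest.fixture(scope="session")
def small_dataset():
    """A smaller dataset for fast pipeline tests (plants still realised)."""
    cfg = cn.GeneratorConfig(n_persons=3000, seed=7)
    persons, events, deaths, truth = cn.generate_dataset(cfg)
    return cfg, persons, events, deaths, truth
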