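import numpy as np
import pytest
from hypothesis import settings

from sitepace import SiteGenerationConfig, generate_site_table

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SiteGenerationConfig:
    """Generator defaults: the 48-site UK trial's reported delay structure."""
    return SiteGenerationConfig(seed=20170612)


@pytest.fixture(scope="session")
def site_records(default_config):
    return generate_site_table(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
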