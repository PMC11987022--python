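import numpy as np
import pytest

from fluorspec.synth import GeneratorConfig, gen_helical_references


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def helical_system(default_config):
    """Default six-carbon helical reference pair with modes (expensive;
    shared across the session)."""
    return gen_helical_references(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
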