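import numpy as np
import pytest

from aridishift import GeneratorConfig, generate_sites
from aridishift.mixed import prepare_analysis_table


@pytest.fixture(scope="session")
def default_table():
    return generate_sites(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def prepared_table(default_table):
    return prepare_analysis_table(default_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
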