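import logging

import pytest

from cllcea.config import default_model_config
from cllcea.synthetic import make_fixture_bundle

logging.getLogger("cllcea").setLevel(logging.ERROR)

BUNDLE_SEED = 3


@pytest.fixture(scope="session")
def bundle():
    """One synthetic fixture bundle shared across the suite."""
    return make_fixture_bundle(seed=BUNDLE_SEED)


@pytest.fixture(scope="session")
def model_config():
    return default_model_config()
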