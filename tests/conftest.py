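import pytest

from commacparma import join_models, preprocess
from commacparma.fixtures import toy_pair


@pytest.fixture(scope="session")
def toy_models():
    return toy_pair()


@pytest.fixture(scope="session")
def toy_community(toy_models):
    return join_models(list(toy_models))


@pytest.fixture(scope="session")
def toy_pre(toy_community):
    """Preprocessed toy community, shared across tests (read-only)."""
    return preprocess(toy_community)
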