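import random

import pytest

from pathterm.defaults import default_session


@pytest.fixture(scope="session")
def session():
    """Default session (packaged tables + default profile). Read-mostly."""
    return default_session()


@pytest.fixture(scope="session")
def graph(session):
    return session.graph


@pytest.fixture()
def rng():
    return random.Random(20140)


@pytest.fixture(scope="session")
def default_registry(session):
    from pathterm.fixtures import generate_registry

    return generate_registry(session.profile, session.graph, seed=0)
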