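import pytest

import annocloud as ac


@pytest.fixture(scope="session")
def fixture_network():
    """The deterministic DNA-replication fixture (seed 1, 8 + 12 nodes)."""
    net, selection = ac.generate_fixture(seed=1)
    return net, set(selection)


@pytest.fixture(scope="session")
def fixture_corpus(fixture_network):
    net, selection = fixture_network
    corpus = ac.build_corpus(net.documents(["name"]))
    return corpus, selection
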