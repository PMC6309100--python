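import pytest

import variodna as v


@pytest.fixture(scope="session")
def graph():
    return v.load_packaged_graph()


@pytest.fixture(scope="session")
def reference():
    return v.make_toy_reference(seed=1, length=10000)


@pytest.fixture(scope="session")
def region_model(reference):
    return v.make_region_model(len(reference))


@pytest.fixture(scope="session")
def corpus(reference):
    """The standard labeled corpus: seed 7, 1000 generated cases + 5 fixed."""
    return v.generate_fixture_set(seed=7, n=1000, reference=reference)
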