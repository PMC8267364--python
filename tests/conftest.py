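import pytest

from abclbd import fixture_matrix, fixture_query


@pytest.fixture(scope="session")
def worked_example():
    """Packaged matrix + vocabulary encoding the cardiac-arrest worked example."""
    matrix, vocab = fixture_matrix()
    return matrix, vocab


@pytest.fixture(scope="session")
def worked_query():
    return fixture_query()
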