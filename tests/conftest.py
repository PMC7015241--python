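import pytest

from fibractin import paper_fixtures


@pytest.fixture(scope="session")
def fixtures():
    """Packaged calibrated fixtures, generated once per session."""
    return paper_fixtures(seed=11)
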