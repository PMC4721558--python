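import pytest

from tmaagree import load_table1


@pytest.fixture(scope="session")
def table1():
    """The packaged 30-case reference study (duplicate TMAs)."""
    return load_table1()
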