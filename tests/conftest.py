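import pytest

from sulfoquant import load_reference_panel


@pytest.fixture(scope="session")
def panel():
    return load_reference_panel()
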