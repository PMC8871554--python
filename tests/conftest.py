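import pytest

from tripod_adherence import load_tripod


@pytest.fixture(scope="session")
def tripod():
    return load_tripod()
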