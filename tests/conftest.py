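import pytest

from tsrnakit import canonical_template, simulate_reference


@pytest.fixture(scope="session")
def canonical():
    return canonical_template()


@pytest.fixture(scope="session")
def small_models():
    return simulate_reference(10, seed=42)
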