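import pytest

from multistate import fixtures


@pytest.fixture
def cdh1_model():
    return fixtures.cdh1_toy()


@pytest.fixture
def translation_model():
    return fixtures.translation_toy()


@pytest.fixture
def all_fixture_models():
    return {name: spec.builder() for name, spec in fixtures.FIXTURES.items()}
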