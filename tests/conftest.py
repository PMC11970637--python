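import pytest

from hillnet import build_cardiacdevnet, build_examplenet


@pytest.fixture
def examplenet():
    return build_examplenet()


@pytest.fixture
def cardiacdevnet():
    return build_cardiacdevnet()
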