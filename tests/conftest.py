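import pytest

from excelsafe.fixtures import validation_table
from excelsafe.rules import RuleConfig


@pytest.fixture(scope="session")
def vtable():
    return validation_table()


@pytest.fixture
def default_config():
    return RuleConfig()
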