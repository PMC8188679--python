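import pytest

from glycorank.glyco_mass import MonosaccharideComposition, PeakList, default_library
from glycorank.glycopeptide import ModificationTable, SearchConfig


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def mod_table():
    return ModificationTable()


@pytest.fixture
def ethcd_config():
    return SearchConfig.ethcd()


@pytest.fixture
def comp():
    """Shorthand composition factory."""
    return MonosaccharideComposition
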