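import pytest

from litternh3 import DesignGrid, MeanStructure


@pytest.fixture(scope="session")
def means():
    return MeanStructure.default()


@pytest.fixture(scope="session")
def wood_grid():
    return DesignGrid("wood_shavings")


@pytest.fixture(scope="session")
def coffee_grid():
    return DesignGrid("coffee_husks")
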