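import pytest

from cophyrec import CostVector, toy_system


@pytest.fixture(scope="session")
def toy():
    return toy_system()


@pytest.fixture(scope="session")
def default_costs():
    return CostVector(1, 1, 2, 4)
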