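import numpy as np
import pytest

from cxcompass import network


@pytest.fixture(scope="session")
def targets():
    return network.make_targets()


@pytest.fixture(scope="session")
def default_model(targets):
    mask = network.build_mask("default")
    return network.optimize_maintenance(mask, targets)


@pytest.fixture(scope="session")
def noduli_model(targets):
    mask = network.build_mask("noduli")
    return network.optimize_maintenance(mask, targets)


@pytest.fixture(scope="session")
def default_modulations(default_model, targets):
    return network.optimize_modulations(default_model, targets)


@pytest.fixture(scope="session")
def noduli_modulations(noduli_model, targets):
    return network.optimize_modulations(noduli_model, targets)
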