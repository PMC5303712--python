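import warnings

import pytest

import astromet as am


@pytest.fixture(scope="session")
def core_model():
    return am.make_core_astrocyte_network()


@pytest.fixture()
def fresh_core_model():
    return am.make_core_astrocyte_network()


@pytest.fixture(scope="session")
def excitatory():
    return am.excitatory_condition()


@pytest.fixture(scope="session")
def constrained_core(core_model, excitatory):
    """Core model with the excitatory physiological bounds applied."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # condition names species outside the core
        return am.apply_condition(core_model, excitatory)


@pytest.fixture(scope="session")
def astrocyte_objectives(constrained_core):
    return am.make_astrocyte_objectives(constrained_core)
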