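import pytest

from oxicea import build_model, default_parameters, default_unit_costs


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def unit_costs():
    return default_unit_costs()


@pytest.fixture(scope="session")
def model(params):
    return build_model(params)


@pytest.fixture(scope="session")
def base_values(params):
    return params.base_values()
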