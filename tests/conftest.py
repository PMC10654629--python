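import pytest

from escc_cea import default_config, evaluate_population


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def base_case_cps_ge1(config):
    return evaluate_population(config, "cps_ge1")


@pytest.fixture(scope="session")
def base_case_cps_1to10(config):
    return evaluate_population(config, "cps_1to10")
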