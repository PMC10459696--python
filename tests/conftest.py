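import pytest

import nanospill as ns


@pytest.fixture(scope="session")
def fuzzy_model():
    return ns.FuzzyRiskModel.default()


@pytest.fixture(scope="session")
def citrate_sphere():
    return ns.NanoparticleSpec(size_nm=10.0, shape="sphere", coating="citrate")


@pytest.fixture(scope="session")
def case1_config():
    return ns.load_scenario("case1_river")


@pytest.fixture(scope="session")
def case2_config():
    return ns.load_scenario("case2_wetland")


@pytest.fixture(scope="session")
def case1_ensemble(case1_config):
    return ns.run_case(case1_config)


@pytest.fixture(scope="session")
def case2_ensemble(case2_config):
    return ns.run_case(case2_config)
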