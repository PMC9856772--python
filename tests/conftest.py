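import pytest
from hypothesis import HealthCheck, settings

import dfucea

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_fixture() -> dfucea.PaperFixture:
    return dfucea.load_paper_parameters()


@pytest.fixture(scope="session")
def defn(paper_fixture) -> dfucea.ModelDefinition:
    return paper_fixture.definition


@pytest.fixture(scope="session")
def params(paper_fixture) -> dfucea.ParameterSet:
    return paper_fixture.model


@pytest.fixture(scope="session")
def strategies(defn):
    return defn.strategies()


@pytest.fixture(scope="session")
def base_result(params, strategies) -> dfucea.CEResult:
    return dfucea.compare_strategies(params, strategies)
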