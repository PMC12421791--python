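import pytest

from farmburden import ParameterSet, generate_claims, generate_fatality_cases


@pytest.fixture(scope="session")
def param_set() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def cases_200(param_set):
    return generate_fatality_cases(200, seed=42)


@pytest.fixture(scope="session")
def claims_1k():
    return generate_claims({"2013-14": 300, "2015-16": 300, "2018-19": 400}, seed=7)
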