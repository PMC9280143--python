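import pytest

from wavedecision import fixtures


@pytest.fixture(scope="session")
def gambling_fixture():
    return fixtures.load_fixture("gambling")


@pytest.fixture(scope="session")
def categorization_fixture():
    return fixtures.load_fixture("categorization")


@pytest.fixture(scope="session")
def pd_fixture():
    return fixtures.load_fixture("prisoners_dilemma")


@pytest.fixture(scope="session")
def gambling_scenarios(gambling_fixture):
    return fixtures.fixture_scenarios(gambling_fixture)


@pytest.fixture(scope="session")
def categorization_scenarios(categorization_fixture):
    return fixtures.fixture_scenarios(categorization_fixture)
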