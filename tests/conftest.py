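import pytest

import snpmeta as sm


@pytest.fixture(scope="session")
def fixture_set() -> sm.StudySet:
    return sm.load_fixture()


@pytest.fixture(scope="session")
def mhatre(fixture_set) -> sm.Study:
    return fixture_set.subset(["Mhatre2015"])[0]


@pytest.fixture(scope="session")
def dominant_effects(fixture_set):
    return [e for _, e in sm.study_effects(fixture_set, sm.GeneticModel.DOMINANT)]


@pytest.fixture
def two_study_set() -> sm.StudySet:
    """A minimal synthetic pair of studies for precondition checks."""
    return sm.simulate_studies(sm.SimScenario(n_studies=2, seed=7))
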