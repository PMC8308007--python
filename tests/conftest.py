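import pytest

from metalrisk import AssessmentConfig, RiskAssessment, paper_fixture


@pytest.fixture(scope="session")
def study():
    """Packaged 36-sample panel and toxicological reference set."""
    return paper_fixture()


@pytest.fixture(scope="session")
def study_records(study):
    return study[0]


@pytest.fixture(scope="session")
def study_refs(study):
    return study[1]


@pytest.fixture(scope="session")
def study_results():
    """Fitted results under the default scenario (70 kg, censor-to-zero,
    table-matching slope-factor convention, 1 and 3 servings)."""
    return RiskAssessment.from_study(config=AssessmentConfig()).fit()
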