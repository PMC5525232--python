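import pytest
from hypothesis import settings

from equiuse.report import run_pipeline
from equiuse.synthetic import GeneratorConfig, generate_survey

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def survey_cfg():
    """Desk-scale survey: the default generating process at 10,000
    respondents per wave (20,000 total)."""
    return GeneratorConfig().scaled(10000, seed=20061)


@pytest.fixture(scope="session")
def survey(survey_cfg):
    """(records, truth) from the default generator."""
    return generate_survey(survey_cfg)


@pytest.fixture(scope="session")
def processed(survey):
    """Records run through the full pipeline: income quartiles, ownership
    split, annualized counts, medicine count."""
    records, _ = survey
    out, stages = run_pipeline(records)
    return out, stages
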