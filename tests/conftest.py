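import pytest
from hypothesis import HealthCheck, settings

from ppgavf.pipeline import PipelineConfig, extract_cohort_features
from ppgavf.synthetic import BeatTemplate, CohortSpec, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: One cohort seed shared by the signal-level integration tests.
COHORT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort():
    """Simulated cohort at the study's default design (5/4/2 subjects)."""
    return generate_cohort(CohortSpec(), COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    """Beat table and per-subject summaries of the default cohort."""
    return extract_cohort_features(default_cohort, PipelineConfig(seed=COHORT_SEED))


@pytest.fixture()
def clean_recording():
    """Noiseless 15-beat pulse train with its ground truth."""
    from ppgavf.synthetic import generate_recording

    template = BeatTemplate(period=0.8, rise_time=0.15, amplitude=1.0)
    return generate_recording(template, 15, 1000.0)
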