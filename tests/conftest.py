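import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def margin_cohort():
    """168-variant cohort with the study's exact per-tool deleterious counts."""
    from snprank import generate_exact_margin_cohort

    return generate_exact_margin_cohort(168, (42, 117, 114), seed=11)


@pytest.fixture(scope="session")
def ptm_registry():
    from snprank import datasets

    return datasets.load_ptm_registry()


@pytest.fixture(scope="session")
def regulatory_rows():
    from snprank import datasets

    return datasets.load_regulatory_sites()
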