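import pytest

from liradsaf import (
    categorize_cohort,
    marginal_fixture,
    sample_cohort,
    published_prevalence_spec,
)


@pytest.fixture(scope="session")
def spec():
    return published_prevalence_spec()


@pytest.fixture(scope="session")
def fixture_cohort(spec):
    """Deterministic cohort matching every published marginal count."""
    return marginal_fixture(spec)


@pytest.fixture(scope="session")
def sampled_cohort(spec):
    """One seeded draw of the default synthetic cohort (473 lesions)."""
    return sample_cohort(spec, seed=1)


@pytest.fixture(scope="session")
def categorized_cohort(sampled_cohort):
    return categorize_cohort(sampled_cohort)
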