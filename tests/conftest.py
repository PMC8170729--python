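import pytest
from hypothesis import HealthCheck, settings

from codredist import synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

SMALL_AGES = ("<1", "1-4", "5-9", "40-44", "65-69", "80-84")


@pytest.fixture(scope="session")
def small_world():
    """2 locations x 2 years x 6 age bands, ~20k deaths."""
    params = syn.WorldParams(
        n_locations=2, years=(2014, 2015), age_groups=SMALL_AGES, total_deaths=20_000.0
    )
    return syn.make_world(params, seed=7)


@pytest.fixture(scope="session")
def hierarchy():
    return syn.fixture_hierarchy()


@pytest.fixture(scope="session")
def garbage_groups(hierarchy):
    return syn.fixture_garbage_groups(hierarchy)
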