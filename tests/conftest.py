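import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table():
    from gridknot.invariants import default_table

    return default_table()


@pytest.fixture(scope="session")
def census_3_7():
    """The full exhaustive census of all 1,859,118 diagrams with GN 3-7."""
    from gridknot.census import census

    return census(3, 7)


@pytest.fixture(scope="session")
def census_5_6():
    from gridknot.census import census

    return census(5, 6)


@pytest.fixture(scope="session")
def unbiased_5_7(census_3_7):
    from gridknot.fluxes import flux_table

    return flux_table(census_3_7, policy="unbiased", gn_min=5, gn_max=7)


@pytest.fixture(scope="session")
def hooked_5_7(census_3_7):
    from gridknot.fluxes import flux_table

    return flux_table(census_3_7, policy="hooked", max_area=1, gn_min=5, gn_max=7)


@pytest.fixture(scope="session")
def gn5_diagrams():
    from gridknot.census import enumerate_grids

    return list(enumerate_grids(5))
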