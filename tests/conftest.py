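import pytest

from fleetreform import (
    SyntheticConfig,
    default_model_params,
    generate_world,
    rates_from_totals,
    worked_example_fixture,
)


@pytest.fixture(scope="session")
def worked_example():
    """The ten-vessel illustrative fleet and its IUU proposal."""
    return worked_example_fixture()


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic world (60 vessels) plus derived allocation rates."""
    world = generate_world(SyntheticConfig(n_vessels=60, n_flag_states=4, seed=11))
    rates = rates_from_totals(
        world.vessels, world.region_catch_t, world.region_revenue_usd, world.subsidy_programs
    )
    return world, rates


@pytest.fixture(scope="session")
def default_world():
    """The shipped default synthetic world and rates (200 vessels, seed 0)."""
    world = generate_world(SyntheticConfig())
    rates = rates_from_totals(
        world.vessels, world.region_catch_t, world.region_revenue_usd, world.subsidy_programs
    )
    return world, rates


@pytest.fixture(scope="session")
def params():
    return default_model_params()
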