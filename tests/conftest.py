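import pytest

from webrds import generate_funnel_fixture, run_pipeline
from webrds.population import PopulationModel, generate_population


@pytest.fixture(scope="session")
def fixture_log():
    """The deterministic funnel fixture under its documented default seed."""
    return generate_funnel_fixture()


@pytest.fixture(scope="session")
def pipeline(fixture_log):
    """Replay + audit + classification of the funnel fixture."""
    return run_pipeline(fixture_log)


@pytest.fixture(scope="session")
def small_graph():
    model = PopulationModel(n=300, degree_distribution=("poisson", 8.0))
    return generate_population(model, rng_seed=11)
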